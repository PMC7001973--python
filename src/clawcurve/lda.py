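"""Linear-discriminant lifestyle models for claw-angle data.

The central statistical object of the package: a Gaussian linear discriminant
analysis (LDA) of raw claw angles (degrees) against the four behavioural
categories, in the convention of the classical R tooling.  The model assumes
each category's angle vector is multivariate normal with its own mean and a
shared (pooled within-class) covariance; discriminant axes solve the
generalized eigenproblem of between- versus within-class scatter and are
normalized so each discriminant has unit pooled within-class variance
("within-class sphering"), which makes the scalings directly comparable
across refits.  The sign of each axis is arbitrary.

Usage follows the statsmodels fit pattern::

    model = LifestyleModel(dataset, metrics=["IU", "OU"])
    res = model.fit()
    print(res.summary())
    res.bootstrap_accuracy(n_iterations=2000, seed=7)
    res.classify_fossils(fossils)

Functional wrappers (``fit_lda``, ``predict_lda``, ``bootstrap_accuracy``,
``project``, ``confidence_ellipse``, ``classify_fossil_set``) are thin
conveniences over these two classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .geometry import ClawMeasures, Metric
from .io import Category, Dataset, FossilRecord

__all__ = [
    "LDAModel",
    "LifestyleModel",
    "LifestyleResults",
    "ClassificationResult",
    "AccuracyReport",
    "EllipseSpec",
    "DegenerateDataError",
    "ModelMismatchError",
    "fit_lda",
    "predict_lda",
    "bootstrap_accuracy",
    "project",
    "confidence_ellipse",
    "classify_fossil_set",
]


class DegenerateDataError(ValueError):
    """Singular pooled covariance (collinear or constant metrics)."""


class ModelMismatchError(ValueError):
    """A prediction input lacks a metric the model requires."""


@dataclass
class LDAModel:
    """Fitted LDA parameters (see module docstring for conventions)."""

    metrics: list[str]
    categories: list[Category]
    class_means: np.ndarray        # (g, p), degrees
    pooled_cov: np.ndarray         # (p, p)
    priors: np.ndarray             # (g,)
    scalings: np.ndarray           # (p, n_axes), within-class sphered
    proportion_of_trace: np.ndarray  # (n_axes,)
    grand_mean: np.ndarray         # (p,) mean of the training rows
    class_counts: np.ndarray       # (g,)

    @property
    def n_axes(self) -> int:
        return self.scalings.shape[1]


@dataclass
class ClassificationResult:
    """Posterior class probabilities for one claw under one model."""

    claw_ref: str
    model_tag: str
    posteriors: dict[Category, float]
    predicted: Category


@dataclass
class AccuracyReport:
    """Out-of-bag bootstrap classification accuracy."""

    model_tag: str
    per_class_accuracy: dict[Category, float]
    total_accuracy: float
    n_iterations: int
    seed: Optional[int]
    n_redrawn: int = 0


@dataclass
class EllipseSpec:
    """Normal-theory confidence ellipse of a group's (LD1, LD2) scores."""

    category: Optional[Category]
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float
    level: float


def _measures_matrix(
    items: Sequence[ClawMeasures], metrics: Sequence[str]
) -> np.ndarray:
    rows = []
    for m in items:
        if not m.has_all(metrics):
            missing = [k for k in metrics if m.get(k) is None]
            raise ModelMismatchError(f"missing metric(s): {', '.join(missing)}")
        rows.append([m.get(k) for k in metrics])
    return np.asarray(rows, dtype=float)


class LifestyleModel:
    """LDA of claw angles against behavioural category.

    Parameters
    ----------
    data : Dataset
        Extant records; rows lacking any of ``metrics`` are dropped.
    metrics : sequence of str or Metric
        Angle subset entering the model, e.g. ``("IU", "OU")`` for the
        bone-only model or ``("IU", "OU", "IS2", "OS")`` for bone + sheath.
    priors : {"frequency", "uniform"} or array
        Class prior probabilities; ``"frequency"`` (default) uses observed
        class frequencies.
    """

    def __init__(
        self,
        data: Dataset,
        metrics: Sequence[Union[Metric, str]] = ("IU", "OU"),
        priors: Union[str, Sequence[float]] = "frequency",
    ) -> None:
        self.metrics = [Metric(m).value for m in metrics]
        self.data = data.subset_complete(self.metrics)
        self.data.check_fittable()
        self.priors_mode = priors
        self._cats = self.data.categories()
        counts = {c: 0 for c in self._cats}
        for r in self.data.records:
            counts[r.category] += 1
        for c, n in counts.items():
            if n <= len(self.metrics):
                raise ValueError(
                    f"category {c.value} has {n} records; needs more than "
                    f"{len(self.metrics)} to estimate within-class scatter"
                )
        self._counts = counts

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        metrics: Sequence[Union[Metric, str]] = ("IU", "OU"),
        priors: Union[str, Sequence[float]] = "frequency",
    ) -> "LifestyleModel":
        """Build from a tidy frame with columns taxon, specimen_id, pes,
        category, body_mass_g and angle columns."""
        from .io import parse_category, parse_pes, SpecimenRecord

        records = []
        for _, row in df.iterrows():
            angles = {
                k: float(row[k])
                for k in ("IU", "OU", "IS", "IS2", "OS")
                if k in df.columns and pd.notna(row[k])
            }
            records.append(
                SpecimenRecord(
                    taxon=str(row.get("taxon", "")),
                    specimen_id=str(row.get("specimen_id", "")),
                    pes=parse_pes(row.get("pes", "unknown")),
                    category=parse_category(row["category"]),
                    body_mass_g=float(row.get("body_mass_g", 1.0)),
                    measures=ClawMeasures(**angles),
                )
            )
        return cls(Dataset(records), metrics=metrics, priors=priors)

    def fit(self) -> "LifestyleResults":
        cats = self._cats
        p = len(self.metrics)
        g = len(cats)
        X = _measures_matrix([r.measures for r in self.data.records], self.metrics)
        y = np.array([cats.index(r.category) for r in self.data.records])
        n = len(y)

        counts = np.array([self._counts[c] for c in cats], dtype=float)
        means = np.vstack([X[y == k].mean(axis=0) for k in range(g)])

        # pooled within-class covariance, divisor N - g
        W = np.zeros((p, p))
        for k in range(g):
            d = X[y == k] - means[k]
            W += d.T @ d
        W /= n - g

        cond = np.linalg.cond(W)
        if not np.isfinite(cond) or cond > 1e12:
            raise DegenerateDataError(
                f"pooled covariance of metrics {self.metrics} is singular or "
                "near-singular (collinear or constant metrics)"
            )

        if isinstance(self.priors_mode, str):
            if self.priors_mode == "frequency":
                priors = counts / counts.sum()
            elif self.priors_mode == "uniform":
                priors = np.full(g, 1.0 / g)
            else:
                raise ValueError(f"unknown priors mode {self.priors_mode!r}")
        else:
            priors = np.asarray(self.priors_mode, dtype=float)
            if priors.shape != (g,) or not math.isclose(priors.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("priors must be one probability per category, summing to 1")

        grand = X.mean(axis=0)
        # between-class scatter of the class means about the grand mean,
        # weighted by class size
        B = np.zeros((p, p))
        for k in range(g):
            d = (means[k] - grand)[:, None]
            B += counts[k] * (d @ d.T)
        B /= max(g - 1, 1)

        # generalized symmetric eigenproblem B v = λ W v; eigh returns
        # eigenvectors with V.T @ W @ V = I (within-class sphering)
        evals, evecs = linalg.eigh(B, W)
        order = np.argsort(evals)[::-1]
        n_axes = min(g - 1, p)
        evals = np.clip(evals[order][:n_axes], 0.0, None)
        scalings = evecs[:, order][:, :n_axes]
        total = evals.sum()
        prop = evals / total if total > 0 else np.full(n_axes, 1.0 / n_axes)

        model = LDAModel(
            metrics=list(self.metrics),
            categories=list(cats),
            class_means=means,
            pooled_cov=W,
            priors=priors,
            scalings=scalings,
            proportion_of_trace=prop,
            grand_mean=grand,
            class_counts=counts,
        )
        return LifestyleResults(self, model)


class LifestyleResults:
    """Results of a fitted :class:`LifestyleModel`."""

    def __init__(self, model: LifestyleModel, params: LDAModel) -> None:
        self.model = model
        self.params = params
        self._w_inv = np.linalg.inv(params.pooled_cov)

    # -- prediction ---------------------------------------------------------

    def _log_posteriors(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        lp = np.empty((X.shape[0], len(p.categories)))
        for k in range(len(p.categories)):
            d = X - p.class_means[k]
            maha = np.einsum("ij,jk,ik->i", d, self._w_inv, d)
            lp[:, k] = math.log(p.priors[k]) - 0.5 * maha
        return lp

    def posterior_matrix(self, X: np.ndarray) -> np.ndarray:
        """Posterior class probabilities for rows of raw angle vectors."""
        lp = self._log_posteriors(np.atleast_2d(np.asarray(X, dtype=float)))
        lp -= lp.max(axis=1, keepdims=True)
        post = np.exp(lp)
        post /= post.sum(axis=1, keepdims=True)
        return post

    def predict(
        self, measures: ClawMeasures, claw_ref: str = "", model_tag: str = ""
    ) -> ClassificationResult:
        """Classify one claw; posteriors are prior × Gaussian density with the
        class mean and pooled covariance, normalized over categories."""
        X = _measures_matrix([measures], self.params.metrics)
        post = self.posterior_matrix(X)[0]
        cats = self.params.categories
        posteriors = {c: float(v) for c, v in zip(cats, post)}
        predicted = cats[int(np.argmax(post))]
        return ClassificationResult(
            claw_ref=claw_ref,
            model_tag=model_tag or "+".join(self.params.metrics),
            posteriors=posteriors,
            predicted=predicted,
        )

    # -- projection / morphospace -------------------------------------------

    def project(self, items: Union[Dataset, Sequence[FossilRecord], np.ndarray]) -> np.ndarray:
        """Discriminant scores: rows centred on the grand mean times scalings."""
        if isinstance(items, Dataset):
            X = _measures_matrix([r.measures for r in items.records], self.params.metrics)
        elif isinstance(items, np.ndarray):
            X = np.atleast_2d(items)
        else:
            X = _measures_matrix([r.measures for r in items], self.params.metrics)
        return (X - self.params.grand_mean) @ self.params.scalings

    def training_scores(self) -> pd.DataFrame:
        scores = self.project(self.model.data)
        cols = [f"LD{i+1}" for i in range(scores.shape[1])]
        df = pd.DataFrame(scores, columns=cols)
        df.insert(0, "category", [r.category.value for r in self.model.data.records])
        df.insert(0, "specimen_id", [r.specimen_id for r in self.model.data.records])
        df.insert(0, "taxon", [r.taxon for r in self.model.data.records])
        return df

    def confidence_ellipses(self, level: float = 0.95) -> list[EllipseSpec]:
        """95% (by default) normal-theory ellipses of each group's LD1/LD2 scores."""
        out = []
        df = self.training_scores()
        for cat in self.params.categories:
            pts = df.loc[df["category"] == cat.value, ["LD1", "LD2"]].to_numpy()
            out.append(confidence_ellipse(pts, level=level, category=cat))
        return out

    # -- bootstrap accuracy --------------------------------------------------

    def bootstrap_accuracy(
        self, n_iterations: int = 2000, seed: Optional[int] = None
    ) -> AccuracyReport:
        """Out-of-bag bootstrap estimate of classification accuracy.

        Each iteration resamples records with replacement, refits the LDA on
        the bootstrap sample, and classifies the out-of-bag records.
        Per-class accuracy is the recall over all out-of-bag instances of the
        class, pooled across iterations; total accuracy weights the per-class
        recalls by class frequency.  Samples missing a class (or too small to
        fit) are redrawn and counted.
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        rng = np.random.default_rng(seed)
        records = self.model.data.records
        n = len(records)
        cats = self.params.categories
        metrics = self.params.metrics
        X = _measures_matrix([r.measures for r in records], metrics)
        y = np.array([cats.index(r.category) for r in records])
        correct = np.zeros(len(cats))
        total = np.zeros(len(cats))
        n_redrawn = 0
        for _ in range(n_iterations):
            while True:
                idx = rng.integers(0, n, size=n)
                in_bag = np.zeros(n, dtype=bool)
                in_bag[idx] = True
                ok = all(
                    np.sum(y[idx] == k) > len(metrics) for k in range(len(cats))
                ) and not in_bag.all()
                if ok:
                    break
                n_redrawn += 1
            sub = Dataset([records[i] for i in idx])
            res = LifestyleModel(sub, metrics=metrics, priors=self.model.priors_mode).fit()
            oob = np.flatnonzero(~in_bag)
            post = res.posterior_matrix(X[oob])
            # argmax in the refit's own category order, then translate to ours
            pred_local = np.argmax(post, axis=1)
            pred = np.array([cats.index(res.params.categories[j]) for j in pred_local])
            for k in range(len(cats)):
                mask = y[oob] == k
                total[k] += mask.sum()
                correct[k] += (pred[mask] == k).sum()
        recall = np.where(total > 0, correct / np.maximum(total, 1), np.nan)
        freq = self.params.class_counts / self.params.class_counts.sum()
        total_acc = float(np.nansum(recall * freq))
        return AccuracyReport(
            model_tag="+".join(metrics),
            per_class_accuracy={c: float(r) for c, r in zip(cats, recall)},
            total_accuracy=total_acc,
            n_iterations=n_iterations,
            seed=seed,
            n_redrawn=n_redrawn,
        )

    # -- reporting -----------------------------------------------------------

    def loadings_frame(self) -> pd.DataFrame:
        p = self.params
        df = pd.DataFrame(
            p.scalings, index=p.metrics, columns=[f"LD{i+1}" for i in range(p.n_axes)]
        )
        df.index.name = "metric"
        return df

    def summary(self) -> str:
        p = self.params
        lines = [
            "Linear discriminant lifestyle model",
            "===================================",
            f"Metrics:            {', '.join(p.metrics)}",
            f"Records:            {int(p.class_counts.sum())}",
            "Class counts:       "
            + ", ".join(f"{c.value}={int(n)}" for c, n in zip(p.categories, p.class_counts)),
            "Priors:             "
            + ", ".join(f"{c.value}={pr:.4f}" for c, pr in zip(p.categories, p.priors)),
            "",
            "Group means (degrees):",
            pd.DataFrame(
                p.class_means, index=[c.value for c in p.categories], columns=p.metrics
            ).to_string(float_format=lambda v: f"{v:9.3f}"),
            "",
            "Coefficients of linear discriminants (within-class sphered):",
            self.loadings_frame().to_string(float_format=lambda v: f"{v:9.6f}"),
            "",
            "Proportion of trace: "
            + ", ".join(
                f"LD{i+1}={v:.4f}" for i, v in enumerate(p.proportion_of_trace)
            ),
        ]
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Serialize fitted parameters as versioned JSON."""
        p = self.params
        payload = {
            "format": "clawcurve-lda",
            "version": 1,
            "metrics": p.metrics,
            "categories": [c.value for c in p.categories],
            "class_means": p.class_means.tolist(),
            "pooled_cov": p.pooled_cov.tolist(),
            "priors": p.priors.tolist(),
            "scalings": p.scalings.tolist(),
            "proportion_of_trace": p.proportion_of_trace.tolist(),
            "grand_mean": p.grand_mean.tolist(),
            "class_counts": p.class_counts.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load(path: Union[str, Path]) -> "LifestyleResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "clawcurve-lda":
            raise ValueError("not a clawcurve LDA model file")
        params = LDAModel(
            metrics=list(payload["metrics"]),
            categories=[Category(c) for c in payload["categories"]],
            class_means=np.asarray(payload["class_means"], dtype=float),
            pooled_cov=np.asarray(payload["pooled_cov"], dtype=float),
            priors=np.asarray(payload["priors"], dtype=float),
            scalings=np.asarray(payload["scalings"], dtype=float),
            proportion_of_trace=np.asarray(payload["proportion_of_trace"], dtype=float),
            grand_mean=np.asarray(payload["grand_mean"], dtype=float),
            class_counts=np.asarray(payload["class_counts"], dtype=float),
        )
        res = LifestyleResults.__new__(LifestyleResults)
        res.model = None  # type: ignore[assignment]
        res.params = params
        res._w_inv = np.linalg.inv(params.pooled_cov)
        return res


# ---------------------------------------------------------------------------
# functional wrappers


def fit_lda(
    data: Dataset,
    metrics: Sequence[Union[Metric, str]],
    priors: Union[str, Sequence[float]] = "frequency",
) -> LifestyleResults:
    """Fit an LDA on a metric subset; see :class:`LifestyleModel`."""
    return LifestyleModel(data, metrics=metrics, priors=priors).fit()


def predict_lda(
    results: LifestyleResults, measures: ClawMeasures, claw_ref: str = ""
) -> ClassificationResult:
    return results.predict(measures, claw_ref=claw_ref)


def bootstrap_accuracy(
    data: Dataset,
    metrics: Sequence[Union[Metric, str]],
    n_iterations: int = 2000,
    seed: Optional[int] = None,
    priors: Union[str, Sequence[float]] = "frequency",
) -> AccuracyReport:
    res = LifestyleModel(data, metrics=metrics, priors=priors).fit()
    return res.bootstrap_accuracy(n_iterations=n_iterations, seed=seed)


def project(
    results: LifestyleResults, items: Union[Dataset, Sequence[FossilRecord], np.ndarray]
) -> np.ndarray:
    return results.project(items)


def confidence_ellipse(
    scores: np.ndarray, level: float = 0.95, category: Optional[Category] = None
) -> EllipseSpec:
    """Normal-theory confidence ellipse of 2-D scores at the chi-square(2)
    quantile of ``level``; axes from the covariance eigendecomposition."""
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional score points")
    if not (0.0 <= level < 1.0):
        raise ValueError("level must be in [0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-12 * max(evals.max(), 1.0):
        raise DegenerateDataError("degenerate score covariance (points collinear)")
    r2 = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    semi = np.sqrt(evals[::-1] * r2)  # major axis first
    major = evecs[:, ::-1][:, 0]
    rotation = math.degrees(math.atan2(major[1], major[0]))
    return EllipseSpec(
        category=category,
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        rotation_deg=rotation,
        level=level,
    )


def classify_fossil_set(
    m1: LifestyleResults,
    m2: Optional[LifestyleResults],
    fossils: Sequence[FossilRecord],
) -> pd.DataFrame:
    """Classify fossil claws with the bone-only model (M1) and, where sheath
    angles exist, the bone+sheath model (M2).

    Returns a tidy frame with one row per claw: M1 posteriors for everyone,
    M2 posteriors where available, both predicted classes and whether the two
    models agree.
    """
    if list(m1.params.metrics) != ["IU", "OU"]:
        raise ValueError("model 1 must be fitted on (IU, OU)")
    rows = []
    cats = m1.params.categories
    for f in fossils:
        ref = f"{f.taxon} {f.specimen_id} ({f.pes.value})"
        r1 = m1.predict(f.measures, claw_ref=ref, model_tag="M1_unguals")
        row: dict[str, object] = {
            "taxon": f.taxon,
            "specimen_id": f.specimen_id,
            "pes": f.pes.value,
        }
        for c in cats:
            row[f"M1_{c.value}"] = r1.posteriors[c]
        row["M1_predicted"] = r1.predicted.value
        if m2 is not None and f.has_sheath:
            r2 = m2.predict(f.measures, claw_ref=ref, model_tag="M2_all")
            for c in m2.params.categories:
                row[f"M2_{c.value}"] = r2.posteriors[c]
            row["M2_predicted"] = r2.predicted.value
            row["models_agree"] = r1.predicted is r2.predicted
        else:
            for c in cats:
                row[f"M2_{c.value}"] = np.nan
            row["M2_predicted"] = ""
            row["models_agree"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
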