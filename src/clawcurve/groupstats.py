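"""Group-wise comparisons of claw angles across behavioural categories.

Covers the classical battery run before any discriminant modelling:

* per-group ordinary least squares of cos(claw angle) on log10(body mass),
  to check for allometric scaling of curvature;
* pairwise two-sample Wilcoxon rank-sum tests per metric, Bonferroni
  corrected over the category pairs (the groups are heteroscedastic, so
  rank tests are preferred over t tests);
* pairwise two-group PERMANOVA on Euclidean distances over a metric subset,
  testing whether multivariate centroids differ, Bonferroni corrected;
* Tukey box-plot summaries per group and metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Metric
from .io import Category, Dataset

__all__ = [
    "RegressionRow",
    "PairwiseMatrix",
    "GroupSummary",
    "transform_angle",
    "transform_mass",
    "fit_group_regressions",
    "pairwise_wilcoxon",
    "pairwise_permanova",
    "permanova_pseudo_f",
    "group_summaries",
    "bonferroni",
]

#: exact Wilcoxon enumeration only when both samples are at most this large
EXACT_WILCOXON_MAX_N = 10


def transform_angle(theta_deg: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Cosine transform of a claw angle in degrees (normalising transform)."""
    return np.cos(np.deg2rad(theta_deg))


def transform_mass(mass_g: Union[float, np.ndarray], base: float = 10.0) -> Union[float, np.ndarray]:
    """Log transform of body mass in grams (default log10)."""
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("body mass must be positive")
    out = np.log(mass_g) / np.log(base)
    return float(out) if out.ndim == 0 else out


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p_raw * n_comparisons)


@dataclass
class RegressionRow:
    """One per-group OLS fit of cos(angle) on log(body mass)."""

    metric: str
    category: Category
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int


@dataclass
class PairwiseMatrix:
    """Symmetric table of Bonferroni-adjusted p-values over category pairs."""

    test: str
    variables: list[str]
    p_adjusted: pd.DataFrame
    n_comparisons: int
    warnings: list[str] = field(default_factory=list)

    def get(self, cat_a: Category, cat_b: Category) -> float:
        return float(self.p_adjusted.loc[cat_a.value, cat_b.value])


@dataclass
class GroupSummary:
    """Tukey box-plot statistics for one metric within one category."""

    metric: str
    category: Category
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: list[float]


def _metric_values(data: Dataset, metric: Union[Metric, str], category: Category) -> np.ndarray:
    name = Metric(metric).value
    vals = [
        r.measures.get(name)
        for r in data.records
        if r.category is category and r.measures.get(name) is not None
    ]
    return np.asarray(vals, dtype=float)


def fit_group_regressions(
    data: Dataset,
    metric: Union[Metric, str],
    log_base: float = 10.0,
    min_n: int = 3,
) -> list[RegressionRow]:
    """Per-category OLS of ``cos(metric angle)`` on ``log(body mass)``.

    Categories with fewer than ``min_n`` complete records are skipped.  The
    slope p-value is the two-sided t test of slope == 0; slopes depend on the
    log base but p-values and R² do not.
    """
    name = Metric(metric).value
    rows: list[RegressionRow] = []
    for cat in data.categories():
        pairs = [
            (r.body_mass_g, r.measures.get(name))
            for r in data.records
            if r.category is cat and r.measures.get(name) is not None
        ]
        if len(pairs) < min_n:
            continue
        mass = transform_mass(np.array([p[0] for p in pairs]), base=log_base)
        y = transform_angle(np.array([p[1] for p in pairs]))
        if np.allclose(y, y[0]):
            # constant response: zero slope, nothing explained
            rows.append(RegressionRow(name, cat, 0.0, float(y[0]), 1.0, 0.0, len(pairs)))
            continue
        fit = stats.linregress(mass, y)
        rows.append(
            RegressionRow(
                metric=name,
                category=cat,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                p_value=float(fit.pvalue),
                r_squared=float(fit.rvalue) ** 2,
                n=len(pairs),
            )
        )
    return rows


def _pair_frame(categories: Sequence[Category]) -> pd.DataFrame:
    names = [c.value for c in categories]
    return pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)


def pairwise_wilcoxon(
    data: Dataset,
    metric: Union[Metric, str],
    correction: str = "bonferroni",
) -> PairwiseMatrix:
    """Pairwise two-sample Wilcoxon rank-sum tests on one metric.

    Exact null distribution when both samples have at most
    ``EXACT_WILCOXON_MAX_N`` observations and no ties; otherwise the normal
    approximation with mid-ranks and tie-corrected variance.  Adjusted
    p-values are ``min(1, p * n_pairs)``.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    name = Metric(metric).value
    cats = data.categories()
    samples = {c: _metric_values(data, name, c) for c in cats}
    cats = [c for c in cats if len(samples[c]) > 0]
    if len(cats) < 2:
        raise ValueError("need at least 2 categories with data")
    pairs = list(combinations(cats, 2))
    mat = _pair_frame(cats)
    warnings: list[str] = []
    for ca, cb in pairs:
        x, y = samples[ca], samples[cb]
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        if no_ties and len(x) <= EXACT_WILCOXON_MAX_N and len(y) <= EXACT_WILCOXON_MAX_N:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p_adj = bonferroni(float(res.pvalue), len(pairs))
        mat.loc[ca.value, cb.value] = p_adj
        mat.loc[cb.value, ca.value] = p_adj
    return PairwiseMatrix(
        test="wilcoxon",
        variables=[name],
        p_adjusted=mat,
        n_comparisons=len(pairs),
        warnings=warnings,
    )


def permanova_pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F for a grouping from a squared Euclidean distance matrix.

    ``F = [SS_between/(g-1)] / [SS_within/(N-g)]`` where ``SS_total`` is the
    sum of squared pairwise distances divided by N and ``SS_within`` the
    analogous per-group sums.
    """
    n = d2.shape[0]
    groups = np.unique(labels)
    g = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _two_group_permanova(
    xa: np.ndarray, xb: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Unadjusted permutation p for a two-group PERMANOVA on Euclidean distances."""
    x = np.vstack([xa, xb])
    n, na = len(x), len(xa)
    labels = np.concatenate([np.zeros(na, dtype=int), np.ones(n - na, dtype=int)])
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    f_obs = permanova_pseudo_f(d2, labels)
    # vectorized over permutations: with group-a indicator z,
    # SS_within = (z'D2z)/(2 na) + ((1-z)'D2(1-z))/(2 nb)
    z = np.empty((n_perm, n))
    for i in range(n_perm):
        z[i] = labels[rng.permutation(n)] == 0
    zd = z @ d2
    s_a = (zd * z).sum(axis=1) / 2.0
    w = 1.0 - z
    s_b = (((w) @ d2) * w).sum(axis=1) / 2.0
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = s_a / na + s_b / (n - na)
    f_perm = (ss_total - ss_within) / (ss_within / (n - 2))
    count = int(np.sum(f_perm >= f_obs))
    return (1 + count) / (1 + n_perm)


def pairwise_permanova(
    data: Dataset,
    metrics: Sequence[Union[Metric, str]],
    n_perm: int = 9999,
    seed: Optional[int] = None,
    correction: str = "bonferroni",
) -> PairwiseMatrix:
    """Pairwise two-group PERMANOVAs on a metric subset.

    Each unordered category pair gets its own two-group permutation test on
    Euclidean distances between the raw angle vectors; ``p = (1 + #{F_perm >=
    F_obs}) / (1 + n_perm)``, then Bonferroni over the number of pairs.  The
    attainable minimum adjusted p is ``n_pairs / (1 + n_perm)``.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    names = [Metric(m).value for m in metrics]
    rng = np.random.default_rng(seed)
    groups: dict[Category, np.ndarray] = {}
    for cat in data.categories():
        rows = [
            [r.measures.get(m) for m in names]
            for r in data.records
            if r.category is cat and r.measures.has_all(names)
        ]
        if len(rows) >= 2:
            groups[cat] = np.asarray(rows, dtype=float)
    cats = list(groups)
    if len(cats) < 2:
        raise ValueError("need at least 2 categories with at least 2 complete records")
    pairs = list(combinations(cats, 2))
    mat = _pair_frame(cats)
    for ca, cb in pairs:
        p_raw = _two_group_permanova(groups[ca], groups[cb], n_perm, rng)
        p_adj = bonferroni(p_raw, len(pairs))
        mat.loc[ca.value, cb.value] = p_adj
        mat.loc[cb.value, ca.value] = p_adj
    return PairwiseMatrix(
        test="permanova",
        variables=names,
        p_adjusted=mat,
        n_comparisons=len(pairs),
    )


def group_summaries(data: Dataset, metric: Union[Metric, str]) -> list[GroupSummary]:
    """Tukey box-plot statistics (median, quartiles, 1.5·IQR whiskers,
    outliers) per behavioural category."""
    name = Metric(metric).value
    out: list[GroupSummary] = []
    for cat in data.categories():
        vals = _metric_values(data, name, cat)
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = sorted(float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)])
        out.append(
            GroupSummary(
                metric=name,
                category=cat,
                n=len(vals),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_lo=float(inside.min()),
                whisker_hi=float(inside.max()),
                outliers=outliers,
            )
        )
    return out


def regressions_to_frame(rows: Sequence[RegressionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "category": r.category.value,
                "slope": r.slope,
                "intercept": r.intercept,
                "p_value": r.p_value,
                "r_squared": r.r_squared,
                "n": r.n,
            }
            for r in rows
        ]
    )


def summaries_to_frame(rows: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": s.metric,
                "category": s.category.value,
                "n": s.n,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_lo": s.whisker_lo,
                "whisker_hi": s.whisker_hi,
                "outliers": ";".join(f"{v:g}" for v in s.outliers),
            }
            for s in rows
        ]
    )
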