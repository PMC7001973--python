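"""Synthetic claw datasets with known ground truth.

Generates extant measurement tables, fossil records with hidden true
categories, and noisy circular-arc outlines, so every stage of the pipeline
(geometry → group statistics → discriminant models → fossil classification)
can be exercised and scored without any external data.

The default four-group configuration mirrors the qualitative structure seen
in real pedal-digit-III claw samples: terrestrial claws flattest, perching
and predatory intermediate (predatory tight), scansorial most hooked; ungual
bone angles lower and less variable than sheath angles; an occasional exactly
flat terrestrial ungual (zero inflation of IU); body masses log-uniform in
36–1930 g.  The numbers are configuration, not estimates of any real sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .geometry import ClawMeasures, ClawOutline, Point2D, Surface
from .io import Category, Dataset, FossilRecord, Pes, SpecimenRecord

__all__ = [
    "GroupGeneratorSpec",
    "ArcSpec",
    "DEFAULT_GROUP_SPECS",
    "default_group_specs",
    "generate_extant",
    "generate_arc_outline",
    "generate_fossils",
]

METRICS = ("IU", "OU", "IS", "IS2", "OS")


@dataclass(frozen=True)
class GroupGeneratorSpec:
    """Ground-truth distribution of one behavioural group.

    ``mean_vector`` holds mean angles (degrees) for (IU, OU, IS, IS2, OS);
    ``covariance`` the metric×metric covariance.  ``zero_inflation`` is the
    probability that IU is exactly 0 (flat unguals; terrestrial only in the
    default configuration).
    """

    category: Category
    mean_vector: tuple[float, ...]
    covariance: np.ndarray
    n: int = 30
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        mv = np.asarray(self.mean_vector, dtype=float)
        if mv.shape != (len(METRICS),):
            raise ValueError(f"mean_vector needs {len(METRICS)} entries")
        if np.any(mv < 0) or np.any(mv > 250):
            raise ValueError("mean angles must lie in [0, 250] degrees")
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        if cov.shape != (len(METRICS), len(METRICS)):
            raise ValueError("covariance must be 5x5")
        evals = np.linalg.eigvalsh((cov + cov.T) / 2)
        if evals.min() < -1e-8 * max(evals.max(), 1.0):
            raise ValueError("covariance must be positive semi-definite")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be a probability")


@dataclass(frozen=True)
class ArcSpec:
    """A circular arc of known central angle with optional coordinate noise."""

    central_angle: float
    radius: float = 1.0
    n_points: int = 100
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.central_angle < 360.0):
            raise ValueError("central_angle must be in (0, 360)")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.radius <= 0 or self.noise_sd < 0:
            raise ValueError("radius must be positive, noise_sd non-negative")


def _corr_to_cov(sd: Sequence[float], rho: float) -> np.ndarray:
    sd = np.asarray(sd, dtype=float)
    corr = np.full((len(sd), len(sd)), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


def default_group_specs(
    n_per_group: int = 30, separation: float = 1.0
) -> list[GroupGeneratorSpec]:
    """Default four-group configuration.

    ``separation`` scales the spread of the group means about their common
    centre (1 = default, 0 = identical means), for testing how classification
    degrades as groups merge.
    """
    means = {
        Category.TERRESTRIAL: (35.0, 62.0, 72.0, 76.0, 85.0),
        Category.PERCHING: (62.0, 88.0, 104.0, 108.0, 112.0),
        Category.PREDATORY: (73.0, 92.0, 112.0, 115.0, 118.0),
        Category.SCANSORIAL: (88.0, 112.0, 132.0, 137.0, 142.0),
    }
    sds = {
        Category.TERRESTRIAL: (11.0, 11.0, 16.0, 16.0, 17.0),
        Category.PERCHING: (12.0, 12.0, 17.0, 17.0, 18.0),
        Category.PREDATORY: (7.0, 7.0, 11.0, 11.0, 12.0),
        Category.SCANSORIAL: (12.0, 12.0, 17.0, 17.0, 18.0),
    }
    grand = np.mean([np.array(v) for v in means.values()], axis=0)
    specs = []
    for cat in (
        Category.TERRESTRIAL,
        Category.PERCHING,
        Category.PREDATORY,
        Category.SCANSORIAL,
    ):
        mu = grand + separation * (np.array(means[cat]) - grand)
        specs.append(
            GroupGeneratorSpec(
                category=cat,
                mean_vector=tuple(np.clip(mu, 0.0, 250.0)),
                covariance=_corr_to_cov(sds[cat], rho=0.6),
                n=n_per_group,
                zero_inflation=0.1 if cat is Category.TERRESTRIAL else 0.0,
            )
        )
    return specs


DEFAULT_GROUP_SPECS = default_group_specs()

_MASS_RANGE = (36.0, 1930.0)


def _truncated_mvn(
    rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray, n: int
) -> np.ndarray:
    """Multivariate normal truncated to [0, 360) per coordinate, by rejection."""
    out = np.empty((0, len(mean)))
    attempts = 0
    while len(out) < n:
        draw = rng.multivariate_normal(mean, cov, size=2 * (n - len(out)) + 8,
                                       method="cholesky")
        keep = draw[np.all((draw >= 0.0) & (draw < 360.0), axis=1)]
        out = np.vstack([out, keep])
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("truncation rejection rate too high for this spec")
    return out[:n]


def _make_records(
    specs: Sequence[GroupGeneratorSpec],
    mass_range: tuple[float, float],
    rng: np.random.Generator,
    taxon_prefix: str,
) -> list[SpecimenRecord]:
    records: list[SpecimenRecord] = []
    counter = 0
    for spec in specs:
        angles = _truncated_mvn(rng, np.asarray(spec.mean_vector), spec.covariance, spec.n)
        if spec.zero_inflation > 0:
            zero = rng.random(spec.n) < spec.zero_inflation
            angles[zero, METRICS.index("IU")] = 0.0
        log_lo, log_hi = np.log10(mass_range[0]), np.log10(mass_range[1])
        masses = 10 ** rng.uniform(log_lo, log_hi, size=spec.n)
        sides = [
            Pes.LEFT if s else Pes.RIGHT for s in rng.integers(0, 2, size=spec.n)
        ]
        for i in range(spec.n):
            counter += 1
            records.append(
                SpecimenRecord(
                    taxon=f"{taxon_prefix} {spec.category.value[:4]}{i+1:03d}",
                    specimen_id=f"SYN-{counter:04d}",
                    pes=sides[i],
                    category=spec.category,
                    body_mass_g=float(masses[i]),
                    measures=ClawMeasures(**dict(zip(METRICS, angles[i]))),
                )
            )
    return records


def generate_extant(
    specs: Optional[Sequence[GroupGeneratorSpec]] = None,
    mass_range: tuple[float, float] = _MASS_RANGE,
    seed: Optional[int] = None,
) -> Dataset:
    """Draw a synthetic extant dataset from per-group truncated multivariate
    normals; deterministic for a fixed seed."""
    specs = list(specs) if specs is not None else default_group_specs()
    if len({s.category for s in specs}) < 2:
        raise ValueError("specs must cover at least 2 categories")
    rng = np.random.default_rng(seed)
    records = _make_records(specs, mass_range, rng, taxon_prefix="Simulornis")
    return Dataset(records, provenance=f"synthetic(seed={seed})")


def generate_arc_outline(spec: ArcSpec) -> tuple[ClawOutline, Point2D, Point2D, float]:
    """A noisy digitized arc: (outline, endpoint A, endpoint B, true angle).

    Points are spaced uniformly along an arc of ``central_angle`` centred on
    the top of a circle of ``radius``; interior points get isotropic Gaussian
    jitter of ``noise_sd``.  ``a`` and ``b`` are the exact arc endpoints.
    """
    rng = np.random.default_rng(spec.seed)
    half = np.deg2rad(spec.central_angle) / 2.0
    # sweep across the top of the circle so the apex is the topmost point
    phi = np.pi / 2 + np.linspace(half, -half, spec.n_points)
    pts = spec.radius * np.column_stack([np.cos(phi), np.sin(phi)])
    a = Point2D(float(pts[0, 0]), float(pts[0, 1]))
    b = Point2D(float(pts[-1, 0]), float(pts[-1, 1]))
    if spec.noise_sd > 0:
        pts[1:-1] += rng.normal(0.0, spec.noise_sd, size=(spec.n_points - 2, 2))
    outline = ClawOutline(
        tuple(Point2D(float(x), float(y)) for x, y in pts), surface=Surface.DORSAL
    )
    return outline, a, b, spec.central_angle


def generate_fossils(
    specs: Optional[Sequence[GroupGeneratorSpec]] = None,
    n_per_category: int = 5,
    sheath_missing_prob: float = 0.5,
    seed: Optional[int] = None,
) -> tuple[list[FossilRecord], list[Category]]:
    """Synthetic fossil claws with hidden true categories.

    Draws from the same group distributions as :func:`generate_extant`, then
    strips the behavioural label and, with probability ``sheath_missing_prob``
    per claw, all sheath angles (leaving a bone-only record).  Returns the
    records and the parallel list of true categories for recovery scoring.
    """
    specs = list(specs) if specs is not None else default_group_specs()
    specs = [replace(s, n=n_per_category) for s in specs]
    rng = np.random.default_rng(seed)
    records = _make_records(specs, _MASS_RANGE, rng, taxon_prefix="Fossilis")
    fossils: list[FossilRecord] = []
    truths: list[Category] = []
    for rec in records:
        m = rec.measures
        if rng.random() < sheath_missing_prob:
            measures = ClawMeasures(IU=m.IU, OU=m.OU)
        else:
            measures = ClawMeasures(IU=m.IU, OU=m.OU, IS=m.IS, IS2=m.IS2, OS=m.OS)
        fossils.append(
            FossilRecord(
                taxon=rec.taxon,
                specimen_id=rec.specimen_id,
                pes=rec.pes,
                measures=measures,
            )
        )
        truths.append(rec.category)
    return fossils, truths
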