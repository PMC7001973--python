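"""Landmark-based claw-angle geometry.

A claw's curvature is quantified as the central angle of the circular arc
fitted through three landmarks on the measured surface: ``A`` at the proximal
end of the surface, ``B`` at the claw tip, and ``X`` at the apex of the
surface (the intersection of the perpendicular bisector of the chord ``AB``
with the digitized outline).  The circle centre ``O`` is the circumcenter of
``A``, ``B``, ``X`` and the claw angle is the angle ``∠AOB`` of the arc that
contains ``X``.  Flat claws (collinear landmarks) measure exactly 0°; strongly
hooked claws may exceed 180°.

Five metric definitions are supported, differing only in where ``A`` and ``B``
sit on the claw:

=======  ========  ==========================================================
metric   surface   meaning
=======  ========  ==========================================================
IU       ventral   inner curvature of the ungual bone (from the flexor
                   tubercle base)
OU       dorsal    outer curvature of the ungual bone
IS       ventral   inner curvature of the keratinous sheath (from the fleshy
                   flexor-tubercle base)
IS2      ventral   inner sheath curvature excluding the toe pad (from the
                   proximal start of the ventral sheath)
OS       dorsal    outer curvature of the keratinous sheath
=======  ========  ==========================================================

Coordinates are unit-free (the angle is invariant under similarity
transforms); angles are always reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Metric",
    "Surface",
    "Point2D",
    "ClawOutline",
    "MetricLandmarks",
    "ClawMeasures",
    "InvalidLandmarksError",
    "ApexNotFoundError",
    "COLLINEARITY_RADIUS_FACTOR",
    "circumcenter",
    "claw_angle",
    "locate_apex",
    "measure_claw",
]


class Metric(str, Enum):
    """The five claw-angle metric definitions."""

    IU = "IU"
    OU = "OU"
    IS = "IS"
    IS2 = "IS2"
    OS = "OS"

    @property
    def surface(self) -> "Surface":
        return Surface.DORSAL if self in (Metric.OU, Metric.OS) else Surface.VENTRAL

    @property
    def is_sheath(self) -> bool:
        return self in (Metric.IS, Metric.IS2, Metric.OS)


class Surface(str, Enum):
    DORSAL = "dorsal"
    VENTRAL = "ventral"


#: Landmarks are treated as collinear (claw angle 0°) when the implied
#: circumradius exceeds this multiple of the chord length |AB|.
COLLINEARITY_RADIUS_FACTOR = 1e6


class InvalidLandmarksError(ValueError):
    """Raised for duplicate or otherwise unusable landmark points."""


class ApexNotFoundError(ValueError):
    """Raised when the chord bisector does not intersect the outline."""


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidLandmarksError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ClawOutline:
    """Digitized polyline of one curved claw surface, ordered proximal→distal."""

    points: tuple[Point2D, ...]
    surface: Surface = Surface.DORSAL

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValueError("outline needs at least 2 points")
        for p, q in zip(pts, pts[1:]):
            if p.x == q.x and p.y == q.y:
                raise ValueError("consecutive outline points must be distinct")

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass(frozen=True)
class MetricLandmarks:
    """Landmarks A, B plus the outline on which apex X is located, for one metric."""

    metric: Metric
    a: Point2D
    b: Point2D
    outline: ClawOutline

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise InvalidLandmarksError(f"{self.metric.value}: landmarks A and B coincide")
        if self.outline.surface is not self.metric.surface:
            raise ValueError(
                f"{self.metric.value} is a {self.metric.surface.value} metric but the "
                f"outline is {self.outline.surface.value}"
            )


@dataclass
class ClawMeasures:
    """The five claw angles of one claw, degrees; sheath metrics may be absent."""

    IU: Optional[float] = None
    OU: Optional[float] = None
    IS: Optional[float] = None
    IS2: Optional[float] = None
    OS: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("IU", "OU", "IS", "IS2", "OS"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not (0.0 <= v < 360.0) or not math.isfinite(v):
                    raise ValueError(f"{name} angle {v} outside [0, 360)")
                setattr(self, name, v)
        if self.IU is None and self.OU is None:
            raise ValueError("at least one ungual angle (IU or OU) must be present")

    def get(self, metric: Metric | str) -> Optional[float]:
        return getattr(self, Metric(metric).value)

    def present(self) -> list[str]:
        return [m for m in ("IU", "OU", "IS", "IS2", "OS") if getattr(self, m) is not None]

    def has_all(self, metrics: Iterable[Metric | str]) -> bool:
        return all(self.get(m) is not None for m in metrics)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {m: getattr(self, m) for m in ("IU", "OU", "IS", "IS2", "OS")}


def _require_distinct(a: Point2D, b: Point2D, x: Point2D) -> None:
    if a == b or a == x or b == x:
        raise InvalidLandmarksError("landmark points must be pairwise distinct")


def circumcenter(
    a: Point2D, b: Point2D, x: Point2D, tol: float = 1.0 / COLLINEARITY_RADIUS_FACTOR
) -> Optional[Point2D]:
    """Centre of the circle through three points, or None when collinear.

    The centre is the intersection of the perpendicular bisectors of the
    chords.  Points are declared collinear (returning ``None``) when the
    implied circumradius exceeds ``|ab| / (2 * tol)``, i.e. the triangle's
    normalized area falls below ``tol``.
    """
    _require_distinct(a, b, x)
    pa, pb, px = a.as_array(), b.as_array(), x.as_array()
    # centre on the centroid: removes catastrophic cancellation for small
    # triangles far from the origin
    centroid = (pa + pb + px) / 3.0
    pa, pb, px = pa - centroid, pb - centroid, px - centroid
    # twice the signed triangle area
    d = 2.0 * ((pa[0] - px[0]) * (pb[1] - px[1]) - (pb[0] - px[0]) * (pa[1] - px[1]))
    scale = max(
        np.linalg.norm(pb - pa), np.linalg.norm(px - pa), np.linalg.norm(px - pb)
    )
    # |d| = 4 * area; circumradius R = |ab||ax||bx| / (4 area).  The collinear
    # cut R > |ab|/(2 tol) is equivalent to normalized area < ~tol.
    if abs(d) <= 2.0 * tol * scale * scale:
        return None
    sa, sb, sx = (pa @ pa), (pb @ pb), (px @ px)
    ux = (sa * (pb[1] - px[1]) + sb * (px[1] - pa[1]) + sx * (pa[1] - pb[1])) / d
    uy = (sa * (px[0] - pb[0]) + sb * (pa[0] - px[0]) + sx * (pb[0] - pa[0])) / d
    return Point2D(float(ux + centroid[0]), float(uy + centroid[1]))


def claw_angle(
    a: Point2D, b: Point2D, x: Point2D, tol: float = 1.0 / COLLINEARITY_RADIUS_FACTOR
) -> float:
    """Central angle ∠AOB, in degrees, of the arc through ``x``.

    Returns a value in [0, 360): 0 exactly for collinear (flat) landmarks,
    more than 180 for strongly hooked claws whose apex subtends a reflex arc.
    Invariant under translation, rotation, reflection, uniform scaling and the
    swap of ``a`` and ``b``.
    """
    _require_distinct(a, b, x)
    # canonical endpoint order makes the a<->b symmetry bit-exact
    if (b.x, b.y) < (a.x, a.y):
        a, b = b, a
    o = circumcenter(a, b, x, tol=tol)
    if o is None:
        return 0.0
    po = o.as_array()
    va, vb, vx = a.as_array() - po, b.as_array() - po, x.as_array() - po
    ta = math.atan2(va[1], va[0])
    tb = math.atan2(vb[1], vb[0])
    tx = math.atan2(vx[1], vx[0])
    # sweep from a to b counter-clockwise and check whether x lies inside it
    sweep_ab = (tb - ta) % (2.0 * math.pi)
    sweep_ax = (tx - ta) % (2.0 * math.pi)
    if sweep_ax <= sweep_ab:
        ang = sweep_ab
    else:
        ang = 2.0 * math.pi - sweep_ab
    return math.degrees(ang) % 360.0


def locate_apex(outline: ClawOutline, a: Point2D, b: Point2D) -> Point2D:
    """Intersect the perpendicular bisector of ``ab`` with the outline.

    Segments are linearly interpolated.  When the bisector crosses the
    polyline more than once, the intersection farthest from the chord ``ab``
    is returned — the apex of the convex measured surface.
    """
    if a == b:
        raise InvalidLandmarksError("landmarks A and B coincide")
    pa, pb = a.as_array(), b.as_array()
    mid = 0.5 * (pa + pb)
    chord = pb - pa  # bisector: points p with (p - mid) @ chord == 0
    pts = outline.as_array()
    f = (pts - mid) @ chord  # signed distance surrogate along the chord direction
    hits: list[np.ndarray] = []
    for i in range(len(pts) - 1):
        f0, f1 = f[i], f[i + 1]
        if f0 == 0.0:
            hits.append(pts[i])
        if (f0 < 0 < f1) or (f1 < 0 < f0):
            t = f0 / (f0 - f1)
            hits.append(pts[i] + t * (pts[i + 1] - pts[i]))
    if f[-1] == 0.0:
        hits.append(pts[-1])
    if not hits:
        raise ApexNotFoundError(
            "perpendicular bisector of AB does not intersect the outline"
        )
    # distance from the chord line; ties broken by the farthest hit
    n = np.array([-chord[1], chord[0]])
    n /= np.linalg.norm(n)
    best = max(hits, key=lambda p: abs(float((p - pa) @ n)))
    return Point2D(float(best[0]), float(best[1]))


def measure_claw(
    landmarks: Sequence[MetricLandmarks],
    tol: float = 1.0 / COLLINEARITY_RADIUS_FACTOR,
) -> ClawMeasures:
    """Measure every supplied metric of one claw.

    For each :class:`MetricLandmarks`, the apex ``X`` is located on the
    outline and the claw angle computed.  Errors are re-raised tagged with the
    metric name.  Metrics not supplied are absent in the result.
    """
    seen: set[Metric] = set()
    values: dict[str, float] = {}
    for lm in landmarks:
        if lm.metric in seen:
            raise ValueError(f"metric {lm.metric.value} supplied more than once")
        seen.add(lm.metric)
        try:
            apex = locate_apex(lm.outline, lm.a, lm.b)
            values[lm.metric.value] = claw_angle(lm.a, lm.b, apex, tol=tol)
        except (ApexNotFoundError, InvalidLandmarksError) as err:
            raise type(err)(f"{lm.metric.value}: {err}") from err
    return ClawMeasures(**values)
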