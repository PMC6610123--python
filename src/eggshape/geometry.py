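"""Landmark geometry for egg shape measurement.

An egg outline is summarised by ten guided landmarks (see
:class:`LandmarkSet`): the two poles ``L1``/``L2`` at the ends of the axis of
rotational symmetry, the endpoints of three transverse chords placed at the
first quartile, midpoint, and third quartile of the curved length axis, and an
optional pair of scale-bar endpoints.  From these the raw pixel quantities
(straight/curved length, the three quartile diameters, the angle of curvature)
and the derived size and shape descriptors are computed:

* ``width  = max(q1, q2, q3)``
* ``aspect ratio = length / width`` (1 = spherical, >1 prolate, <1 oblate)
* ``asymmetry = max(q1, q3) / min(q1, q3) - 1`` (0 = front/back symmetric)
* ``angle of curvature`` = central angle of the circular arc through the two
  poles and the midpoint of the ``q2`` chord (0 = straight egg); reported only
  for eggs with aspect ratio > 1.
* ``volume = (1/6)·π·l·w²`` for a rotationally symmetric ellipsoid, or
  ``(1/6)·π·l·w·b`` when a distinct breadth ``b`` is known.

Millimetre quantities are produced only when a scale bar is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Point2D",
    "LandmarkSet",
    "ArcFit",
    "RawMeasurement",
    "DerivedMeasurement",
    "InvalidLandmarkError",
    "circumcircle",
    "angle_of_curvature",
    "curved_length",
    "measure_from_landmarks",
    "derive_measurement",
    "ellipsoid_volume",
    "read_landmarks_tsv",
    "write_landmarks_tsv",
    "write_derived_tsv",
]

#: Three points are treated as collinear when twice the triangle area falls
#: below this fraction of the squared point span (avoids fitting
#: astronomically large circles to nearly straight configurations).
COLLINEAR_TOL = 1e-9


class InvalidLandmarkError(ValueError):
    """Raised for degenerate landmark input (duplicate points, zero width...)."""


@dataclass(frozen=True)
class Point2D:
    """A 2-D point in pixel coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidLandmarkError(f"non-finite coordinates: ({self.x}, {self.y})")

    def __iter__(self):
        yield self.x
        yield self.y


def distance(p: Point2D, q: Point2D) -> float:
    return math.hypot(p.x - q.x, p.y - q.y)


def midpoint(p: Point2D, q: Point2D) -> Point2D:
    return Point2D((p.x + q.x) / 2.0, (p.y + q.y) / 2.0)


@dataclass(frozen=True)
class LandmarkSet:
    """The ten guided landmarks of one egg image.

    ``L1``/``L2`` are the poles, ``M1``/``M2`` the endpoints of the mid (q2)
    chord, ``Q1a``/``Q1b`` and ``Q3a``/``Q3b`` the endpoints of the first- and
    third-quartile chords.  ``S1``/``S2`` mark the ends of the published scale
    bar whose physical length is ``scale_bar_mm``; all three must be supplied
    together or not at all.
    """

    L1: Point2D
    L2: Point2D
    M1: Point2D
    M2: Point2D
    Q1a: Point2D
    Q1b: Point2D
    Q3a: Point2D
    Q3b: Point2D
    S1: Optional[Point2D] = None
    S2: Optional[Point2D] = None
    scale_bar_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for a, b, name in (
            (self.L1, self.L2, "poles L1/L2"),
            (self.M1, self.M2, "q2 chord M1/M2"),
            (self.Q1a, self.Q1b, "q1 chord"),
            (self.Q3a, self.Q3b, "q3 chord"),
        ):
            if distance(a, b) == 0.0:
                raise InvalidLandmarkError(f"{name} endpoints coincide")
        has_scale = (self.S1 is not None, self.S2 is not None, self.scale_bar_mm is not None)
        if any(has_scale) and not all(has_scale):
            raise InvalidLandmarkError("scale bar requires S1, S2 and scale_bar_mm together")
        if self.scale_bar_mm is not None:
            if self.scale_bar_mm <= 0:
                raise InvalidLandmarkError("scale_bar_mm must be positive")
            if distance(self.S1, self.S2) == 0.0:
                raise InvalidLandmarkError("scale bar endpoints coincide")

    @property
    def px_per_mm(self) -> Optional[float]:
        """Pixels per millimetre implied by the scale bar, or None."""
        if self.scale_bar_mm is None:
            return None
        return distance(self.S1, self.S2) / self.scale_bar_mm


@dataclass(frozen=True)
class ArcFit:
    """Circular arc through three points.

    ``central_angle_deg`` is the angle at ``center`` subtended by the arc from
    the first to the third point *passing through* the second.  Collinear
    input is flagged with an infinite radius and a zero angle.
    """

    center: Optional[Point2D]
    radius: float
    central_angle_deg: float
    collinear: bool = False


@dataclass(frozen=True)
class RawMeasurement:
    """Raw pixel quantities read off one landmark set."""

    straight_length_px: float
    curved_length_px: float
    q1_px: float
    q2_px: float
    q3_px: float
    curvature_deg: float

    def __post_init__(self) -> None:
        for name in ("straight_length_px", "curved_length_px", "q1_px", "q2_px", "q3_px"):
            if getattr(self, name) <= 0:
                raise InvalidLandmarkError(f"{name} must be positive")
        if self.curvature_deg < 0:
            raise InvalidLandmarkError("curvature_deg must be non-negative")
        # Arc length can never undercut its chord; allow fp slack.
        if self.curved_length_px < self.straight_length_px * (1 - 1e-12):
            raise InvalidLandmarkError("curved length shorter than straight length")


@dataclass(frozen=True)
class DerivedMeasurement:
    """Derived size and shape descriptors of one egg.

    Millimetre fields are present iff a scale was supplied.  Curvature is
    undefined (None) for eggs with aspect ratio <= 1.
    """

    aspect_ratio: float
    asymmetry: float
    curvature_deg: Optional[float] = None
    curvature_rad: Optional[float] = None
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    volume_mm3: Optional[float] = None


# ---------------------------------------------------------------------------
# arc fitting

def _require_distinct(*points: Point2D) -> None:
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if distance(points[i], points[j]) == 0.0:
                raise InvalidLandmarkError("duplicate points supplied to arc fit")


def circumcircle(p: Point2D, q: Point2D, r: Point2D) -> ArcFit:
    """Fit the circle through three points; the arc runs p -> q -> r.

    The returned central angle is the angle subtended at the centre by the
    arc from ``p`` to ``r`` that passes through ``q``.  Collinear triples are
    returned with the ``collinear`` flag, an infinite radius, and angle 0.
    """
    _require_distinct(p, q, r)
    ax, ay = p.x, p.y
    bx, by = q.x, q.y
    cx, cy = r.x, r.y
    cross = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    span_sq = max(
        (bx - ax) ** 2 + (by - ay) ** 2,
        (cx - ax) ** 2 + (cy - ay) ** 2,
        (cx - bx) ** 2 + (cy - by) ** 2,
    )
    if abs(cross) < COLLINEAR_TOL * span_sq:
        return ArcFit(center=None, radius=math.inf, central_angle_deg=0.0, collinear=True)

    # Perpendicular-bisector intersection, solved in closed form.
    d = 2.0 * cross
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    center = Point2D(ux, uy)
    radius = distance(center, p)

    # Angle between the centre->p and centre->r directions, in [0, pi] ...
    v1 = (p.x - ux, p.y - uy)
    v2 = (r.x - ux, r.y - uy)
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    crs = v1[0] * v2[1] - v1[1] * v2[0]
    base = math.atan2(abs(crs), dot)
    # ... then pick minor vs major arc depending on which side q lies on:
    # the minor arc lies on the opposite side of the chord p-r from the centre.
    side_q = _side(p, r, q)
    side_c = _side(p, r, center)
    if side_q == 0 or side_q != side_c:
        angle = base
    else:
        angle = 2.0 * math.pi - base
    return ArcFit(center=center, radius=radius, central_angle_deg=math.degrees(angle))


def _side(a: Point2D, b: Point2D, p: Point2D) -> int:
    s = (b.x - a.x) * (p.y - a.y) - (b.y - a.y) * (p.x - a.x)
    return 0 if s == 0 else (1 if s > 0 else -1)


def angle_of_curvature(L1: Point2D, L2: Point2D, mid_q2: Point2D) -> float:
    """Angle of curvature in degrees: the central angle of the arc through
    the two poles and the midpoint of the q2 chord; 0 for a straight egg."""
    return circumcircle(L1, mid_q2, L2).central_angle_deg


def curved_length(L1: Point2D, L2: Point2D, mid_q2: Point2D) -> float:
    """Arc length along the fitted length axis; the chord length when straight."""
    fit = circumcircle(L1, mid_q2, L2)
    if fit.collinear:
        return distance(L1, L2)
    return fit.radius * math.radians(fit.central_angle_deg)


# ---------------------------------------------------------------------------
# measurement

def measure_from_landmarks(lm: LandmarkSet) -> RawMeasurement:
    """Raw pixel measurements of one landmark set.

    Straight length is |L1-L2|; the quartile diameters are the chord lengths;
    curvature and curved length come from the arc through the poles and the
    midpoint of the q2 chord.
    """
    mid_q2 = midpoint(lm.M1, lm.M2)
    return RawMeasurement(
        straight_length_px=distance(lm.L1, lm.L2),
        curved_length_px=curved_length(lm.L1, lm.L2, mid_q2),
        q1_px=distance(lm.Q1a, lm.Q1b),
        q2_px=distance(lm.M1, lm.M2),
        q3_px=distance(lm.Q3a, lm.Q3b),
        curvature_deg=angle_of_curvature(lm.L1, lm.L2, mid_q2),
    )


def derive_measurement(raw: RawMeasurement, px_per_mm: Optional[float] = None) -> DerivedMeasurement:
    """Derive shape descriptors (and mm sizes, when scaled) from raw pixels.

    Curvature is copied through only for prolate eggs (aspect ratio > 1);
    for rounder eggs the fitted arc is too poorly conditioned to interpret.
    """
    if px_per_mm is not None and px_per_mm <= 0:
        raise InvalidLandmarkError("px_per_mm must be positive")
    width_px = max(raw.q1_px, raw.q2_px, raw.q3_px)
    if width_px <= 0:
        raise InvalidLandmarkError("zero egg width")
    aspect_ratio = raw.straight_length_px / width_px
    asymmetry = max(raw.q1_px, raw.q3_px) / min(raw.q1_px, raw.q3_px) - 1.0

    curv_deg: Optional[float] = None
    curv_rad: Optional[float] = None
    if aspect_ratio > 1.0:
        curv_deg = raw.curvature_deg
        curv_rad = math.radians(raw.curvature_deg)

    length_mm = width_mm = volume = None
    if px_per_mm is not None:
        length_mm = raw.straight_length_px / px_per_mm
        width_mm = width_px / px_per_mm
        volume = ellipsoid_volume(length_mm, width_mm)
    return DerivedMeasurement(
        aspect_ratio=aspect_ratio,
        asymmetry=asymmetry,
        curvature_deg=curv_deg,
        curvature_rad=curv_rad,
        length_mm=length_mm,
        width_mm=width_mm,
        volume_mm3=volume,
    )


def ellipsoid_volume(l: float, w: float, b: Optional[float] = None) -> float:
    """Ellipsoid volume (1/6)πlwb, or (1/6)πlw² for a rotationally
    symmetric egg when no breadth is given.  Units follow the inputs."""
    if l <= 0 or w <= 0 or (b is not None and b <= 0):
        raise InvalidLandmarkError("ellipsoid dimensions must be positive")
    if b is None:
        b = w
    return math.pi * l * w * b / 6.0


# ---------------------------------------------------------------------------
# landmark TSV dialect

_LANDMARK_POINTS = ("L1", "L2", "M1", "M2", "Q1a", "Q1b", "Q3a", "Q3b")
_LANDMARK_COLUMNS = [f"{n}{ax}" for n in _LANDMARK_POINTS for ax in ("x", "y")] + [
    "S1x", "S1y", "S2x", "S2y", "scale_bar_mm",
]


def read_landmarks_tsv(path) -> list[LandmarkSet]:
    """Read a tab-delimited landmark file (one row per image).

    Columns are ``L1x..Q3by`` plus optional ``S1x..S2y`` and ``scale_bar_mm``;
    scale fields are left empty when no scale bar was published.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _LANDMARK_COLUMNS[:16] if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        pts = {n: Point2D(float(row[f"{n}x"]), float(row[f"{n}y"])) for n in _LANDMARK_POINTS}
        scale_kwargs = {}
        if "scale_bar_mm" in df.columns and pd.notna(row.get("scale_bar_mm")):
            scale_kwargs = dict(
                S1=Point2D(float(row["S1x"]), float(row["S1y"])),
                S2=Point2D(float(row["S2x"]), float(row["S2y"])),
                scale_bar_mm=float(row["scale_bar_mm"]),
            )
        out.append(LandmarkSet(**pts, **scale_kwargs))
    return out


def write_landmarks_tsv(landmarks: Iterable[LandmarkSet], path) -> None:
    rows = []
    for lm in landmarks:
        row = {}
        for n in _LANDMARK_POINTS:
            p = getattr(lm, n)
            row[f"{n}x"], row[f"{n}y"] = p.x, p.y
        if lm.scale_bar_mm is not None:
            row.update(S1x=lm.S1.x, S1y=lm.S1.y, S2x=lm.S2.x, S2y=lm.S2.y,
                       scale_bar_mm=lm.scale_bar_mm)
        rows.append(row)
    pd.DataFrame(rows, columns=_LANDMARK_COLUMNS).to_csv(path, sep="\t", index=False)


def write_derived_tsv(measurements: Sequence[DerivedMeasurement], path) -> None:
    """Write derived measurements as TSV (length/width/volume in mm where a
    scale bar was present; angle of curvature in radians)."""
    rows = []
    for m in measurements:
        rows.append({
            "length": m.length_mm,
            "width": m.width_mm,
            "volume": m.volume_mm3,
            "aspect_ratio": m.aspect_ratio,
            "asymmetry": m.asymmetry,
            "angle_of_curvature": m.curvature_rad,
        })
    df = pd.DataFrame(rows, columns=["length", "width", "volume", "aspect_ratio",
                                     "asymmetry", "angle_of_curvature"])
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.9g")
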