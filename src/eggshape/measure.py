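"""Automated landmark placement and closed-loop measurement.

Replaces the human annotator in the guided landmark protocol: locate the two
poles (the boundary points of steepest margin curvature), drop the guide
constructions (the perpendicular bisector of the length axis, the fitted arc
and its quarter-point perpendiculars), read the resulting chords off the
outline, and derive the shape parameters.  Optional isotropic landmark jitter
emulates human clicking error for accuracy studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
from shapely.geometry import LineString, LinearRing, Point as ShapelyPoint

from .geometry import (
    DerivedMeasurement,
    LandmarkSet,
    Point2D,
    circumcircle,
    derive_measurement,
    measure_from_landmarks,
)
from .simulate import (
    InfeasibleShapeError,
    ShapeParams,
    Silhouette,
    bend_profile,
    scale_silhouette,
    straight_profile,
)

__all__ = [
    "MeasurementError",
    "PoleResult",
    "RecoveryRow",
    "find_poles",
    "place_guides",
    "measure_silhouette",
    "recovery_report",
    "boundary_from_mask",
    "measure_mask",
]


class MeasurementError(RuntimeError):
    """Raised when a guide construction fails to intersect the outline."""


class PoleResult(NamedTuple):
    L1: Point2D
    L2: Point2D
    #: True when no two curvature maxima were found (e.g. a near-perfect
    #: circle) and maximally separated boundary points were used instead.
    fallback: bool = False


@dataclass(frozen=True)
class RecoveryRow:
    """One row of a closed-loop accuracy report.

    Discrepancies follow the actual-minus-measured convention: a positive
    curvature discrepancy means the protocol underestimates curvature.
    """

    truth: ShapeParams
    mean_aspect_ratio: float
    mean_asymmetry: float
    mean_curvature_deg: float          # NaN where curvature is undefined
    mean_discrepancy_aspect_ratio: float
    mean_discrepancy_asymmetry: float
    mean_discrepancy_curvature_deg: float
    n_reps: int


# ---------------------------------------------------------------------------
# pole detection

def _resample_closed(boundary: np.ndarray, n: int) -> np.ndarray:
    pts = np.vstack([boundary, boundary[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perim = cum[-1]
    targets = np.linspace(0.0, perim, n, endpoint=False)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return np.column_stack([x, y])


def _boundary_curvature(pts: np.ndarray, window_frac: float = 0.015) -> np.ndarray:
    """Smoothed turning-angle curvature at each resampled boundary vertex.

    Signed turning angles are boxcar-averaged over an arc-length window
    before taking magnitudes, so pixel-staircase noise on rasterised
    boundaries cancels instead of accumulating.
    """
    n = len(pts)
    edges = np.roll(pts, -1, axis=0) - pts
    h = np.linalg.norm(edges, axis=1).mean()
    ang = np.arctan2(edges[:, 1], edges[:, 0])
    turn = (np.diff(np.concatenate([ang, ang[:1]])) + np.pi) % (2 * np.pi) - np.pi
    turn = np.roll(turn, 1)  # turn[i]: angle at vertex i between edges i-1 and i
    w = max(3, int(round(window_frac * n)) | 1)
    # circular boxcar smoothing via a rolling sum over the tripled array
    csum = np.concatenate([[0.0], np.cumsum(np.tile(turn, 3))])
    half = w // 2
    idx = np.arange(n) + n
    smoothed = (csum[idx + half + 1] - csum[idx - half]) / w
    return np.abs(smoothed) / h


def _local_maxima_circular(values: np.ndarray) -> np.ndarray:
    prev = np.roll(values, 1)
    nxt = np.roll(values, -1)
    return np.nonzero((values > prev) & (values >= nxt))[0]


def _suppress_nearby(candidates: np.ndarray, scores: np.ndarray, n: int,
                     radius: int, keep: int = 12) -> list[int]:
    """Greedy circular non-maximum suppression of curvature peaks."""
    order = candidates[np.argsort(scores[candidates])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(min(abs(i - j), n - abs(i - j)) > radius for j in kept):
            kept.append(int(i))
        if len(kept) >= keep:
            break
    return kept


def find_poles(sil: Silhouette, n_resample: int = 2048) -> PoleResult:
    """Locate the two egg poles: boundary points of steepest margin curvature.

    Candidate poles are local maxima of the smoothed boundary curvature;
    among candidates separated by at least a quarter of the perimeter each
    way, the pair maximising the product of curvature scores wins (ties go to
    larger separation, then lowest boundary index).  Degenerate outlines with
    fewer than two maxima fall back to two points at maximal boundary
    separation, flagged.
    """
    pts = _resample_closed(sil.boundary, n_resample)
    kappa = _boundary_curvature(pts)
    n = len(pts)
    maxima = _local_maxima_circular(kappa)
    # a pole must stand out against the typical margin curvature; a perfect
    # circle has only noise-level "maxima" and falls through to the fallback
    maxima = maxima[kappa[maxima] >= 1.1 * np.median(kappa)]

    best: Optional[tuple] = None
    if len(maxima) >= 2:
        candidates = _suppress_nearby(maxima, kappa, n, radius=int(0.05 * n))
        for ii in range(len(candidates)):
            for jj in range(ii + 1, len(candidates)):
                i, j = sorted((candidates[ii], candidates[jj]))
                sep = min(j - i, n - (j - i))
                if sep < 0.25 * n:
                    continue
                key = (kappa[i] * kappa[j], sep, -i, -j)
                if best is None or key > best[0]:
                    best = (key, i, j)
    perim = np.linalg.norm(np.diff(np.vstack([sil.boundary, sil.boundary[:1]]), axis=0),
                           axis=1).sum()
    radius = 2.0 * perim * max(3, int(round(0.015 * n)) | 1) / n
    if best is None:
        i, j = 0, n // 2
        p1 = _refine_pole(pts[i], sil.boundary, radius)
        p2 = _refine_pole(pts[j], sil.boundary, radius)
        return PoleResult(Point2D(*p1), Point2D(*p2), fallback=True)

    _, i, j = best
    p1 = _refine_pole(pts[i], sil.boundary, radius)
    p2 = _refine_pole(pts[j], sil.boundary, radius)
    return PoleResult(Point2D(*p1), Point2D(*p2), fallback=False)


def _refine_pole(p: np.ndarray, boundary: np.ndarray, radius: float) -> np.ndarray:
    """Refine a smoothed-curvature peak to the sharpest original vertex.

    The smoothing window displaces a sharp-tip peak by up to half its width;
    among original vertices within ``radius`` of the estimate, the one with
    the largest (near-maximal) interior turning angle closest to the estimate
    is the pole.  On smooth boundaries (no vertex markedly sharper than its
    neighbours) the estimate itself is kept.
    """
    d = np.linalg.norm(boundary - p, axis=1)
    near = np.nonzero(d <= radius)[0]
    if len(near) == 0:
        return p
    prev = boundary[(near - 1) % len(boundary)]
    nxt = boundary[(near + 1) % len(boundary)]
    v1 = boundary[near] - prev
    v2 = nxt - boundary[near]
    ang1 = np.arctan2(v1[:, 1], v1[:, 0])
    ang2 = np.arctan2(v2[:, 1], v2[:, 0])
    turn = np.abs((ang2 - ang1 + np.pi) % (2 * np.pi) - np.pi)
    top = turn.max()
    if top < 0.2:  # no genuinely sharp vertex nearby: smooth boundary
        return p
    sharp = near[turn >= 0.8 * top]
    k = sharp[np.argmin(d[sharp])]
    return boundary[k]


# ---------------------------------------------------------------------------
# guide construction

def _line_through(p: np.ndarray, direction: np.ndarray, reach: float) -> LineString:
    d = direction / np.linalg.norm(direction)
    return LineString([tuple(p - reach * d), tuple(p + reach * d)])


def _intersection_points(ring: LinearRing, line: LineString) -> List[np.ndarray]:
    inter = ring.intersection(line)
    if inter.is_empty:
        return []
    geoms = getattr(inter, "geoms", [inter])
    pts = []
    for g in geoms:
        if isinstance(g, ShapelyPoint):
            pts.append(np.array([g.x, g.y]))
        else:  # collinear overlap: keep the segment endpoints
            pts.extend(np.asarray(g.coords))
    return pts


def _nearest_pair_across(pts: Sequence[np.ndarray], origin: np.ndarray,
                         direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The crossing nearest ``origin`` on each side along ``direction``
    (used when the origin lies inside the egg)."""
    d = direction / np.linalg.norm(direction)
    pos = [(float(np.dot(p - origin, d)), p) for p in pts]
    fwd = [pp for pp in pos if pp[0] > 1e-12]
    bwd = [pp for pp in pos if pp[0] < -1e-12]
    if not fwd or not bwd:
        raise MeasurementError("guide line does not cross the outline on both sides")
    a = min(fwd, key=lambda t: t[0])[1]
    b = max(bwd, key=lambda t: t[0])[1]
    return a, b


def _nearest_two(pts: Sequence[np.ndarray], origin: np.ndarray,
                 direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two distinct crossings nearest ``origin`` along ``direction``
    (for strongly curved eggs the chord midpoint lies outside the egg, so
    both crossings can sit on the same side of it)."""
    d = direction / np.linalg.norm(direction)
    pos = sorted(((float(np.dot(p - origin, d)), p) for p in pts), key=lambda t: abs(t[0]))
    for i in range(1, len(pos)):
        if abs(pos[i][0] - pos[0][0]) > 1e-9:
            return pos[0][1], pos[i][1]
    raise MeasurementError("guide line does not cross the outline twice")


def place_guides(sil: Silhouette, poles: PoleResult | tuple[Point2D, Point2D]) -> LandmarkSet:
    """Drop the guided landmarks on a silhouette given its poles.

    M1/M2 are the intersections of the perpendicular bisector of L1-L2 with
    the outline; a circular arc is fitted through L1, mid(M1M2), L2; the
    quartile chords are the intersections with the outline of the
    perpendiculars to that arc at the two points bisecting each half-arc.
    Intersections nearest the arc are used.  Scale-bar landmarks are
    synthesised from the silhouette's ``px_per_mm`` metadata.
    """
    L1, L2 = poles[0], poles[1]
    ring = LinearRing(np.vstack([sil.boundary, sil.boundary[:1]]))
    bbox = sil.boundary.max(axis=0) - sil.boundary.min(axis=0)
    reach = 4.0 * float(np.hypot(*bbox))

    p1 = np.array([L1.x, L1.y])
    p2 = np.array([L2.x, L2.y])
    axis = p2 - p1
    perp = np.array([-axis[1], axis[0]])
    mid = (p1 + p2) / 2.0

    m_pts = _intersection_points(ring, _line_through(mid, perp, reach))
    if len(m_pts) < 2:
        raise MeasurementError("perpendicular bisector does not cross the outline twice")
    m1, m2 = _nearest_two(m_pts, mid, perp)
    mid_q2 = (m1 + m2) / 2.0

    arc = circumcircle(L1, Point2D(*mid_q2), L2)
    if arc.collinear:
        centers = [p1 + 0.25 * axis, p1 + 0.75 * axis]
        normals = [perp, perp]
    else:
        c = np.array([arc.center.x, arc.center.y])
        theta = math.radians(arc.central_angle_deg)
        a1 = math.atan2(p1[1] - c[1], p1[0] - c[0])
        # traversal direction from L1 towards L2 that passes through mid_q2
        best_dir, best_d = 1.0, math.inf
        for direction in (1.0, -1.0):
            g = a1 + direction * theta / 2.0
            probe = c + arc.radius * np.array([math.cos(g), math.sin(g)])
            dd = float(np.linalg.norm(probe - mid_q2))
            if dd < best_d:
                best_dir, best_d = direction, dd
        centers, normals = [], []
        for t in (0.25, 0.75):
            g = a1 + best_dir * theta * t
            u = np.array([math.cos(g), math.sin(g)])
            centers.append(c + arc.radius * u)
            normals.append(u)

    chords = []
    for ctr, nrm in zip(centers, normals):
        pts = _intersection_points(ring, _line_through(ctr, nrm, reach))
        if len(pts) < 2:
            raise MeasurementError("quartile guide line does not cross the outline")
        chords.append(_nearest_pair_across(pts, ctr, nrm))
    (q1a, q1b), (q3a, q3b) = chords

    scale_kwargs = {}
    if sil.px_per_mm is not None:
        scale_kwargs = dict(S1=Point2D(0.0, 0.0), S2=Point2D(float(sil.px_per_mm), 0.0),
                            scale_bar_mm=1.0)
    return LandmarkSet(
        L1=L1, L2=L2,
        M1=Point2D(*m1), M2=Point2D(*m2),
        Q1a=Point2D(*q1a), Q1b=Point2D(*q1b),
        Q3a=Point2D(*q3a), Q3b=Point2D(*q3b),
        **scale_kwargs,
    )


def _jitter_landmarks(lm: LandmarkSet, jitter_px: float, rng: np.random.Generator,
                      ring: Optional[LinearRing] = None) -> LandmarkSet:
    """Displace each landmark by isotropic Gaussian noise of scale jitter_px.

    When the outline ``ring`` is given, margin landmarks (poles and chord
    endpoints) are projected back onto it after displacement — a human drops
    these points on the egg margin, so click error slides along the outline
    rather than leaving it.  Scale-bar landmarks stay unconstrained.
    """
    def j(p: Optional[Point2D], constrain: bool) -> Optional[Point2D]:
        if p is None:
            return None
        dx, dy = rng.normal(0.0, jitter_px, size=2)
        q = Point2D(p.x + dx, p.y + dy)
        if constrain and ring is not None:
            snapped = ring.interpolate(ring.project(ShapelyPoint(q.x, q.y)))
            q = Point2D(snapped.x, snapped.y)
        return q

    return LandmarkSet(
        L1=j(lm.L1, True), L2=j(lm.L2, True), M1=j(lm.M1, True), M2=j(lm.M2, True),
        Q1a=j(lm.Q1a, True), Q1b=j(lm.Q1b, True), Q3a=j(lm.Q3a, True), Q3b=j(lm.Q3b, True),
        S1=j(lm.S1, False), S2=j(lm.S2, False), scale_bar_mm=lm.scale_bar_mm,
    )


def measure_silhouette(sil: Silhouette, jitter_px: float = 0.0,
                       seed: int = 0) -> DerivedMeasurement:
    """Full automated protocol: find poles, place guides, measure, derive.

    With ``jitter_px > 0`` every landmark is displaced by isotropic Gaussian
    noise of that scale (seeded) before measurement, emulating human
    clicking; with zero jitter the result is deterministic and the seed is
    ignored.
    """
    poles = find_poles(sil)
    lm = place_guides(sil, poles)
    if jitter_px > 0:
        ring = LinearRing(np.vstack([sil.boundary, sil.boundary[:1]]))
        lm = _jitter_landmarks(lm, jitter_px, np.random.default_rng(seed), ring=ring)
    raw = measure_from_landmarks(lm)
    return derive_measurement(raw, px_per_mm=lm.px_per_mm)


# ---------------------------------------------------------------------------
# closed-loop accuracy report

def _build_silhouette(params: ShapeParams, n_points: int, px_per_unit: float) -> Silhouette:
    sil = straight_profile(ShapeParams(params.aspect_ratio, params.asymmetry, 0.0),
                           n_points=n_points)
    if params.curvature_deg > 0:
        sil = bend_profile(sil, params.curvature_deg)
    return scale_silhouette(sil, px_per_unit)


def recovery_report(grid: Sequence[ShapeParams], n_reps: int = 5,
                    jitter_px: float = 0.0, seed: int = 0,
                    px_per_unit: float = 200.0, n_points: int = 384) -> List[RecoveryRow]:
    """Closed-loop accuracy assessment over a parameter grid.

    Each grid point is simulated at ``px_per_unit`` pixels per unit axis
    length and measured ``n_reps`` times; discrepancies are reported as
    actual minus mean measured.  Landmark guides are placed once per
    silhouette and only the landmark jitter is redrawn between repeats.
    Measurement failures yield NaN cells rather than aborting the report.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(len(grid), n_reps))

    rows: List[RecoveryRow] = []
    for gi, params in enumerate(grid):
        try:
            sil = _build_silhouette(params, n_points, px_per_unit)
            poles = find_poles(sil)
            lm0 = place_guides(sil, poles)
        except (MeasurementError, InfeasibleShapeError):
            rows.append(RecoveryRow(params, math.nan, math.nan, math.nan,
                                    math.nan, math.nan, math.nan, n_reps))
            continue
        ring = LinearRing(np.vstack([sil.boundary, sil.boundary[:1]]))

        ars, asyms, curvs = [], [], []
        for rep in range(n_reps):
            lm = lm0
            if jitter_px > 0:
                lm = _jitter_landmarks(lm0, jitter_px,
                                       np.random.default_rng(int(rep_seeds[gi, rep])),
                                       ring=ring)
            try:
                m = derive_measurement(measure_from_landmarks(lm), px_per_mm=lm.px_per_mm)
            except Exception:
                continue
            ars.append(m.aspect_ratio)
            asyms.append(m.asymmetry)
            if m.curvature_deg is not None:
                curvs.append(m.curvature_deg)

        mean_ar = float(np.mean(ars)) if ars else math.nan
        mean_asym = float(np.mean(asyms)) if asyms else math.nan
        mean_curv = float(np.mean(curvs)) if curvs else math.nan
        curvature_defined = params.aspect_ratio > 1 and curvs
        rows.append(RecoveryRow(
            truth=params,
            mean_aspect_ratio=mean_ar,
            mean_asymmetry=mean_asym,
            mean_curvature_deg=mean_curv,
            mean_discrepancy_aspect_ratio=params.aspect_ratio - mean_ar,
            mean_discrepancy_asymmetry=params.asymmetry - mean_asym,
            mean_discrepancy_curvature_deg=(params.curvature_deg - mean_curv
                                            if curvature_defined else math.nan),
            n_reps=n_reps,
        ))
    return rows


# ---------------------------------------------------------------------------
# raster input

def boundary_from_mask(mask: np.ndarray) -> np.ndarray:
    """Extract the outer outline of a binary mask as an (N, 2) x/y polygon."""
    from skimage import measure as sk_measure

    contours = sk_measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise MeasurementError("no foreground outline found in mask")
    contour = max(contours, key=len)
    # find_contours returns (row, col); convert to (x, y)
    return np.column_stack([contour[:, 1], contour[:, 0]])


def measure_mask(mask: np.ndarray, px_per_mm: Optional[float] = None,
                 jitter_px: float = 0.0, seed: int = 0) -> DerivedMeasurement:
    """Measure an egg from a binary raster mask."""
    boundary = boundary_from_mask(mask)
    # truth parameters of a raster input are unknown; a placeholder is stored
    sil = Silhouette(boundary=boundary, truth=ShapeParams(1.0),
                     px_per_mm=px_per_mm if px_per_mm is not None else 1.0)
    if px_per_mm is None:
        poles = find_poles(sil)
        lm = place_guides(sil, poles)
        lm = LandmarkSet(L1=lm.L1, L2=lm.L2, M1=lm.M1, M2=lm.M2,
                         Q1a=lm.Q1a, Q1b=lm.Q1b, Q3a=lm.Q3a, Q3b=lm.Q3b)
        if jitter_px > 0:
            lm = _jitter_landmarks(lm, jitter_px, np.random.default_rng(seed))
        return derive_measurement(measure_from_landmarks(lm))
    return measure_silhouette(sil, jitter_px=jitter_px, seed=seed)
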