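"""Parametric egg-silhouette simulator.

Generates closed egg outlines with *known* aspect ratio, asymmetry and angle
of curvature, so that the measurement pipeline can be validated closed-loop:
simulate with known parameters, measure, compare.

Construction
------------
A straight egg is built from a diameter profile ``d(s)`` on the unit-length
axis ``s in [0, 1]`` interpolated through the anchors ``(0, 0)``,
``(0.25, q1)``, ``(0.5, q2)``, ``(0.75, q3)``, ``(1, 0)`` with a monotone
shape-preserving cubic (PCHIP).  The anchors are chosen so that the
definitional formulas return the requested parameters exactly:
``q1 = q2 = D`` and ``q3 = D / (1 + asymmetry)`` with ``D = 1/aspect_ratio``,
hence ``width = max(q1, q2, q3) = D`` and the wider quartile sits at the L1
end.

A curved egg is produced by mapping the midline onto a circular arc of
central angle θ whose *chord* equals the original axis length, offsetting the
boundary radially by ±d(s)/2 (diameters are preserved along arc length).
Keeping the chord fixed keeps the straight-length aspect ratio of the bent
silhouette equal to the requested one, so all three parameters remain
simultaneously recoverable by the measurement protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from shapely.geometry import Polygon

__all__ = [
    "ShapeParams",
    "Silhouette",
    "InfeasibleShapeError",
    "diameter_profile",
    "straight_profile",
    "bend_profile",
    "rasterize",
    "validation_grid",
    "scale_silhouette",
    "transform_silhouette",
]


class InfeasibleShapeError(ValueError):
    """Raised when the requested parameters cannot yield a simple outline."""


@dataclass(frozen=True)
class ShapeParams:
    """Generative shape triple: aspect ratio, asymmetry, curvature angle.

    Curved oblate/spherical eggs (aspect ratio <= 1 with nonzero curvature)
    are outside the validated parameter space and are rejected.
    """

    aspect_ratio: float
    asymmetry: float = 0.0
    curvature_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.aspect_ratio <= 0:
            raise InfeasibleShapeError("aspect_ratio must be positive")
        if self.asymmetry < 0:
            raise InfeasibleShapeError("asymmetry must be non-negative")
        if not 0 <= self.curvature_deg < 180:
            raise InfeasibleShapeError("curvature_deg must lie in [0, 180)")
        if self.curvature_deg > 0 and self.aspect_ratio <= 1:
            raise InfeasibleShapeError("curved eggs require aspect_ratio > 1")


@dataclass
class Silhouette:
    """A closed egg outline with its generating truth parameters.

    ``boundary`` is an (N, 2) array of vertices in order (not repeated at the
    end); ``px_per_mm`` records the physical scale of the coordinate units.
    """

    boundary: np.ndarray
    truth: ShapeParams
    px_per_mm: float = 1.0
    mask: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2 or len(self.boundary) < 3:
            raise InfeasibleShapeError("boundary must be an (N>=3, 2) array")
        if self.px_per_mm <= 0:
            raise InfeasibleShapeError("px_per_mm must be positive")
        poly = Polygon(self.boundary)
        if not poly.is_simple or poly.area <= 0:
            raise InfeasibleShapeError("boundary is self-intersecting or degenerate")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


def _quartile_diameters(params: ShapeParams) -> tuple[float, float, float]:
    D = 1.0 / params.aspect_ratio
    return D, D, D / (1.0 + params.asymmetry)


def diameter_profile(params: ShapeParams) -> Callable[[np.ndarray], np.ndarray]:
    """Diameter profile d(s) on [0, 1] hitting the quartile anchors exactly.

    A monotone (per-segment) cubic through (0,0), (0.25,q1), (0.5,q2),
    (0.75,q3), (1,0): interior derivatives follow the shape-preserving PCHIP
    rule, so the profile never rings negative and its maximum equals
    max(q1, q2, q3) exactly.  The end derivatives are clamped to zero, giving
    the outline spindle-shaped pole tips — the margin turns sharpest at the
    poles for every parameter combination, prolate or oblate, which is what
    pole detection relies on.
    """
    from scipy.interpolate import CubicHermiteSpline

    q1, q2, q3 = _quartile_diameters(params)
    x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    y = np.array([0.0, q1, q2, q3, 0.0])
    dydx = PchipInterpolator(x, y).derivative()(x)
    dydx[0] = dydx[-1] = 0.0  # cusped tips; clamping keeps monotonicity
    return CubicHermiteSpline(x, y, dydx)


def _axis_samples(n_points: int) -> np.ndarray:
    # one side of the outline gets m = 4k+1 samples so the quartiles land on
    # grid nodes exactly
    if n_points < 64:
        raise InfeasibleShapeError("n_points must be at least 64")
    m_side = n_points // 2 + 1
    k = max(16, math.ceil((m_side - 1) / 4))
    return np.linspace(0.0, 1.0, 4 * k + 1)


def straight_profile(params: ShapeParams, n_points: int = 384) -> Silhouette:
    """Simulate a straight egg silhouette of unit axis length.

    ``n_points`` is the approximate total number of boundary vertices (it is
    rounded so that the quartile stations fall exactly on vertices).
    """
    if params.curvature_deg != 0:
        raise InfeasibleShapeError("straight_profile requires curvature_deg = 0")
    s = _axis_samples(n_points)
    d = diameter_profile(params)(s)
    top = np.column_stack([s, d / 2.0])
    bottom = np.column_stack([s[::-1][1:-1], -d[::-1][1:-1] / 2.0])
    boundary = np.vstack([top, bottom])
    return Silhouette(boundary=boundary, truth=params, px_per_mm=1.0)


def bend_profile(sil: Silhouette, curvature_deg: float) -> Silhouette:
    """Bend a straight silhouette onto a circular arc of central angle θ.

    The midline becomes an arc whose chord equals the original axis length L,
    i.e. radius R = L / (2 sin(θ/2)); boundary points are offset radially by
    their original half-diameter, so diameters along arc length are preserved
    and the arc through the deformed poles and the q2 midpoint has central
    angle θ exactly.  θ = 0 returns the silhouette unchanged.
    """
    if not 0 <= curvature_deg < 180:
        raise InfeasibleShapeError("curvature_deg must lie in [0, 180)")
    if curvature_deg == 0:
        return replace(sil, boundary=sil.boundary.copy())
    if sil.truth.curvature_deg != 0:
        raise InfeasibleShapeError("bend_profile expects a straight input silhouette")

    xy = sil.boundary
    x0, x1 = xy[:, 0].min(), xy[:, 0].max()
    L = x1 - x0
    theta = math.radians(curvature_deg)
    R = L / (2.0 * math.sin(theta / 2.0))
    offsets = xy[:, 1]
    if np.any(R - np.abs(offsets) <= 0):
        raise InfeasibleShapeError("bend radius smaller than half-diameter; outline would self-intersect")

    t = (xy[:, 0] - x0) / L                       # arc-length fraction along midline
    phi = theta * (t - 0.5)
    cx, cy = x0 + L / 2.0, R * math.cos(theta / 2.0)
    ux, uy = np.sin(phi), -np.cos(phi)            # outward radial direction
    r = R + offsets
    boundary = np.column_stack([cx + r * ux, cy + r * uy])
    truth = replace(sil.truth, curvature_deg=curvature_deg)
    return Silhouette(boundary=boundary, truth=truth, px_per_mm=sil.px_per_mm)


def rasterize(sil: Silhouette, px_per_unit: float, margin_px: int = 2) -> np.ndarray:
    """Scan-convert the outline into a binary mask (uint8, foreground = 1).

    The long axis must span at least 100 px at the requested resolution.
    Rasterisation is deterministic; the mask is also stored on the input
    silhouette's ``mask`` attribute.
    """
    from skimage.draw import polygon as _sk_polygon

    xy = sil.boundary
    spans = xy.max(axis=0) - xy.min(axis=0)
    if max(spans) * px_per_unit < 100:
        raise InfeasibleShapeError("resolution too low: long axis must be >= 100 px")
    origin = xy.min(axis=0)
    cols = (xy[:, 0] - origin[0]) * px_per_unit + margin_px
    rows = (xy[:, 1] - origin[1]) * px_per_unit + margin_px
    shape = (
        int(math.ceil(rows.max())) + margin_px + 1,
        int(math.ceil(cols.max())) + margin_px + 1,
    )
    rr, cc = _sk_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    sil.mask = mask
    return mask


def validation_grid() -> List[ShapeParams]:
    """The 24-point validation grid: aspect ratios {0.5, 1, 2, 6} x
    asymmetries {0, 0.2, 0.8} x curvatures {0, 30, 120}, with nonzero
    curvature omitted for aspect ratio <= 1."""
    grid: List[ShapeParams] = []
    for ar in (0.5, 1.0, 2.0, 6.0):
        for asym in (0.0, 0.2, 0.8):
            curvatures = (0.0,) if ar <= 1 else (0.0, 30.0, 120.0)
            for curv in curvatures:
                grid.append(ShapeParams(ar, asym, curv))
    return grid


def scale_silhouette(sil: Silhouette, factor: float) -> Silhouette:
    """Uniformly scale coordinates by ``factor`` (px_per_mm scales with it)."""
    if factor <= 0:
        raise InfeasibleShapeError("scale factor must be positive")
    return Silhouette(boundary=sil.boundary * factor, truth=sil.truth,
                      px_per_mm=sil.px_per_mm * factor)


def transform_silhouette(sil: Silhouette, angle_deg: float = 0.0,
                         dx: float = 0.0, dy: float = 0.0,
                         reflect: bool = False) -> Silhouette:
    """Apply a rigid motion (rotation, translation, optional reflection)."""
    xy = sil.boundary.copy()
    if reflect:
        xy[:, 1] = -xy[:, 1]
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    xy = xy @ rot.T + np.array([dx, dy])
    return Silhouette(boundary=xy, truth=sil.truth, px_per_mm=sil.px_per_mm)
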