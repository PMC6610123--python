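"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def brute_force_circle(p, q, r, levels=14, grid=13):
    """Independent circle-through-three-points oracle.

    The centre is seeded from a derivation independent of the implementation's
    perpendicular-bisector solve — the circumradius formula R = abc / (4K)
    and the intersection of the two radius-R circles centred on p and q —
    then refined by a multi-resolution grid search minimising the spread of
    the three point distances.  Returns (center xy, radius).
    """
    pts = np.array([p, q, r], dtype=float)
    a = np.linalg.norm(pts[1] - pts[2])
    b = np.linalg.norm(pts[0] - pts[2])
    c = np.linalg.norm(pts[0] - pts[1])
    area2 = abs((pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
                - (pts[1, 1] - pts[0, 1]) * (pts[2, 0] - pts[0, 0]))
    r_est = a * b * c / (2.0 * area2)  # = abc / (4 * area)

    def spread(center):
        d = np.linalg.norm(center - pts, axis=1)
        return d.max() - d.min()

    # two candidate centres: intersections of circles of radius R about p, q
    mid = (pts[0] + pts[1]) / 2.0
    half = c / 2.0
    height = math.sqrt(max(0.0, r_est ** 2 - half ** 2))
    perp = np.array([-(pts[1] - pts[0])[1], (pts[1] - pts[0])[0]]) / c
    candidates = [mid + height * perp, mid - height * perp]
    center = min(candidates, key=spread)

    width = 0.1 * r_est
    offsets = np.linspace(-0.5, 0.5, grid)
    ox, oy = np.meshgrid(offsets, offsets)
    unit = np.column_stack([ox.ravel(), oy.ravel()])
    for _ in range(levels):
        cand = np.vstack([center + unit * width, center])
        d = np.linalg.norm(cand[:, None, :] - pts[None, :, :], axis=2)
        cost = d.max(axis=1) - d.min(axis=1)
        center = cand[int(np.argmin(cost))]
        width /= 3.0
    radius = float(np.linalg.norm(center - pts, axis=1).mean())
    return center, radius


def oracle_arc_angle(p, q, r):
    """Central angle (degrees) of the arc p->r through q, from the oracle fit.

    Uses the chord/inradius relation θ = 2·arcsin(chord / 2R), taking the
    major arc when q lies on the same side of the chord as the centre.
    """
    center, radius = brute_force_circle(p, q, r)
    chord = np.linalg.norm(np.asarray(r, dtype=float) - np.asarray(p, dtype=float))
    base = 2.0 * math.asin(min(1.0, chord / (2.0 * radius)))

    def side(a, b, x):
        s = (b[0] - a[0]) * (x[1] - a[1]) - (b[1] - a[1]) * (x[0] - a[0])
        return 0 if s == 0 else (1 if s > 0 else -1)

    if side(p, r, q) == side(p, r, center) and side(p, r, q) != 0:
        base = 2.0 * math.pi - base
    return math.degrees(base), radius


def random_triple(rng, min_cross=0.05):
    """A well-conditioned random point triple (not nearly collinear)."""
    while True:
        pts = rng.uniform(-10, 10, size=(3, 2))
        cross = abs((pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
                    - (pts[1, 1] - pts[0, 1]) * (pts[2, 0] - pts[0, 0]))
        span_sq = max(np.sum((pts[i] - pts[j]) ** 2)
                      for i in range(3) for j in range(i + 1, 3))
        if cross > min_cross * span_sq:
            return pts


@pytest.fixture(scope="session")
def grid_silhouettes():
    """All 24 validation-grid silhouettes at 300 px per unit axis length."""
    from eggshape import (ShapeParams, bend_profile, scale_silhouette,
                          straight_profile, validation_grid)

    out = []
    for params in validation_grid():
        sil = straight_profile(ShapeParams(params.aspect_ratio, params.asymmetry, 0.0))
        if params.curvature_deg > 0:
            sil = bend_profile(sil, params.curvature_deg)
        out.append((params, scale_silhouette(sil, 300.0)))
    return out
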