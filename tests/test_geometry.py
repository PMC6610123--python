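"""Measurement geometry: arc fitting, landmark measurement, derivations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eggshape import (
    InvalidLandmarkError,
    LandmarkSet,
    Point2D,
    RawMeasurement,
    angle_of_curvature,
    circumcircle,
    curved_length,
    derive_measurement,
    ellipsoid_volume,
    measure_from_landmarks,
)

from conftest import oracle_arc_angle, random_triple

SQRT3_2 = math.sqrt(3.0) / 2.0


class TestCircumcircle:
    def test_symmetric_unit_circle_points(self):
        fit = circumcircle(Point2D(-1, 0), Point2D(0, 1), Point2D(1, 0))
        assert fit.center.x == pytest.approx(0.0, abs=1e-12)
        assert fit.center.y == pytest.approx(0.0, abs=1e-12)
        assert fit.radius == pytest.approx(1.0, rel=1e-12)

    def test_collinear_points_flagged(self):
        fit = circumcircle(Point2D(0, 0), Point2D(1, 0), Point2D(2, 0))
        assert fit.collinear
        assert math.isinf(fit.radius)
        assert fit.central_angle_deg == 0.0

    def test_right_triangle_center(self):
        # perpendicular-bisector intersection solved by hand: (1.5, 2), r=2.5
        fit = circumcircle(Point2D(0, 0), Point2D(3, 0), Point2D(0, 4))
        assert (fit.center.x, fit.center.y) == pytest.approx((1.5, 2.0), rel=1e-12)
        assert fit.radius == pytest.approx(2.5, rel=1e-12)

    def test_duplicate_points_rejected(self):
        with pytest.raises(InvalidLandmarkError):
            circumcircle(Point2D(0, 0), Point2D(0, 0), Point2D(1, 1))

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p, q, r = random_triple(rng)
            fit = circumcircle(Point2D(*p), Point2D(*q), Point2D(*r))
            _, oracle_radius = oracle_arc_angle(p, q, r)
            assert fit.radius == pytest.approx(oracle_radius, rel=1e-6)


class TestAngleOfCurvature:
    @pytest.mark.parametrize(
        "L1, L2, mid, expected",
        [
            # straight egg
            ((-1, 0), (1, 0), (0, 0), 0.0),
            # points at 210°, 330°, 270° on the unit circle subtend 120°
            ((-SQRT3_2, -0.5), (SQRT3_2, -0.5), (0, -1), 120.0),
            # semicircle
            ((-1, 0), (1, 0), (0, -1), 180.0),
        ],
    )
    def test_constructed_arcs(self, L1, L2, mid, expected):
        angle = angle_of_curvature(Point2D(*L1), Point2D(*L2), Point2D(*mid))
        assert angle == pytest.approx(expected, abs=1e-9)

    def test_major_arc_detected(self):
        # midpoint on the far side of the circle: the arc through it is major
        angle = angle_of_curvature(Point2D(-SQRT3_2, -0.5), Point2D(SQRT3_2, -0.5),
                                   Point2D(0, 1))
        assert angle == pytest.approx(240.0, abs=1e-9)


class TestCurvedLength:
    def test_collinear_equals_chord(self):
        assert curved_length(Point2D(0, 0), Point2D(2, 0), Point2D(1, 0)) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "L1, L2, mid, expected",
        [
            ((-SQRT3_2, -0.5), (SQRT3_2, -0.5), (0, -1), 2 * math.pi / 3),
            ((-1, 0), (1, 0), (0, -1), math.pi),
        ],
    )
    def test_unit_circle_arcs(self, L1, L2, mid, expected):
        got = curved_length(Point2D(*L1), Point2D(*L2), Point2D(*mid))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_arc_never_shorter_than_chord(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p, q, r = random_triple(rng, min_cross=0.01)
            chord = np.linalg.norm(r - p)
            arc = curved_length(Point2D(*p), Point2D(*r), Point2D(*q))
            assert arc >= chord * (1 - 1e-12)


def _symmetric_landmarks(q1=5.0, q3=5.0, scale=None):
    kwargs = {}
    if scale is not None:
        kwargs = dict(S1=Point2D(0, 0), S2=Point2D(scale, 0), scale_bar_mm=1.0)
    return LandmarkSet(
        L1=Point2D(0, 0), L2=Point2D(0, 10),
        M1=Point2D(-2.5, 5), M2=Point2D(2.5, 5),
        Q1a=Point2D(-q1 / 2, 2.5), Q1b=Point2D(q1 / 2, 2.5),
        Q3a=Point2D(-q3 / 2, 7.5), Q3b=Point2D(q3 / 2, 7.5),
        **kwargs,
    )


class TestMeasureFromLandmarks:
    def test_symmetric_straight_egg(self):
        raw = measure_from_landmarks(_symmetric_landmarks())
        assert raw.straight_length_px == pytest.approx(10.0)
        assert raw.q1_px == raw.q2_px == raw.q3_px == pytest.approx(5.0)
        assert raw.curvature_deg == pytest.approx(0.0, abs=1e-9)
        assert raw.curved_length_px == pytest.approx(10.0)

    def test_unequal_quartile_chords(self):
        raw = measure_from_landmarks(_symmetric_landmarks(q1=6.0, q3=5.0))
        assert raw.q1_px == pytest.approx(6.0)
        assert raw.q3_px == pytest.approx(5.0)

    @given(st.floats(-180, 180), st.floats(-50, 50), st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle_deg, dx, dy):
        lm = _symmetric_landmarks(q1=6.0, q3=4.5)
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)

        def move(p):
            return Point2D(c * p.x - s * p.y + dx, s * p.x + c * p.y + dy)

        moved = LandmarkSet(**{name: move(getattr(lm, name))
                               for name in ("L1", "L2", "M1", "M2", "Q1a", "Q1b", "Q3a", "Q3b")})
        raw0 = measure_from_landmarks(lm)
        raw1 = measure_from_landmarks(moved)
        for field in ("straight_length_px", "curved_length_px", "q1_px", "q2_px",
                      "q3_px", "curvature_deg"):
            assert getattr(raw1, field) == pytest.approx(getattr(raw0, field), abs=1e-7)

    def test_scale_bar_consistency_enforced(self):
        with pytest.raises(InvalidLandmarkError):
            LandmarkSet(
                L1=Point2D(0, 0), L2=Point2D(0, 10),
                M1=Point2D(-2.5, 5), M2=Point2D(2.5, 5),
                Q1a=Point2D(-2.5, 2.5), Q1b=Point2D(2.5, 2.5),
                Q3a=Point2D(-2.5, 7.5), Q3b=Point2D(2.5, 7.5),
                scale_bar_mm=1.0,  # S1/S2 missing
            )


class TestDeriveMeasurement:
    def test_scaled_symmetric_egg(self):
        raw = measure_from_landmarks(_symmetric_landmarks(scale=1.0))
        m = derive_measurement(raw, px_per_mm=1.0)
        assert m.width_mm == pytest.approx(5.0)
        assert m.aspect_ratio == pytest.approx(2.0)
        assert m.asymmetry == pytest.approx(0.0)
        assert m.volume_mm3 == pytest.approx(math.pi / 6 * 10 * 25, rel=1e-12)

    def test_oblate_egg_has_no_curvature(self):
        raw = RawMeasurement(straight_length_px=5, curved_length_px=5,
                             q1_px=10, q2_px=10, q3_px=10, curvature_deg=12.0)
        m = derive_measurement(raw)
        assert m.aspect_ratio == pytest.approx(0.5)
        assert m.curvature_deg is None and m.curvature_rad is None

    def test_asymmetry_formula(self):
        raw = RawMeasurement(straight_length_px=10, curved_length_px=10,
                             q1_px=1.2, q2_px=1.2, q3_px=1.0, curvature_deg=0.0)
        assert derive_measurement(raw).asymmetry == pytest.approx(0.2)

    def test_no_scale_no_mm_fields(self):
        m = derive_measurement(measure_from_landmarks(_symmetric_landmarks()))
        assert m.length_mm is None and m.width_mm is None and m.volume_mm3 is None

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    def test_asymmetry_symmetric_and_nonnegative(self, q1, q3):
        raw = RawMeasurement(straight_length_px=20, curved_length_px=20,
                             q1_px=q1, q2_px=max(q1, q3), q3_px=q3, curvature_deg=0.0)
        swapped = RawMeasurement(straight_length_px=20, curved_length_px=20,
                                 q1_px=q3, q2_px=max(q1, q3), q3_px=q1, curvature_deg=0.0)
        a1 = derive_measurement(raw).asymmetry
        a2 = derive_measurement(swapped).asymmetry
        assert a1 == pytest.approx(a2, rel=1e-12)
        assert a1 >= 0.0
        if q1 == q3:
            assert a1 == 0.0


class TestEllipsoidVolume:
    def test_unit_sphere(self):
        assert ellipsoid_volume(1, 1, 1) == pytest.approx(math.pi / 6, rel=1e-12)

    def test_rotationally_symmetric_form(self):
        assert ellipsoid_volume(1, 0.5) == pytest.approx(math.pi * 0.25 / 6, rel=1e-12)

    def test_triaxial_form_and_reduction(self):
        assert ellipsoid_volume(1, 0.5, 0.25) == pytest.approx(math.pi * 0.125 / 6, rel=1e-12)
        assert ellipsoid_volume(1, 0.5, 0.5) == ellipsoid_volume(1, 0.5)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(InvalidLandmarkError):
            ellipsoid_volume(1.0, 0.0)
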