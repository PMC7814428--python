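"""Core geometry: hinge axis, rigid rotation, slope measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from owhto import (
    ColumnModel,
    OsteotomyPlan,
    closed_form_pts,
    hinge_axis,
    opened_slope_direction,
    rotate_about_axis,
    sagittal_slope_angle,
    transform_point,
)
from owhto.geometry import DegenerateDirectionError, InvalidPlanError

angles = st.floats(-30.0, 30.0)
corrections = st.floats(0.0, 30.0)


def scipy_rotate(v, axis, angle_deg):
    """Independent rotation oracle via scipy's Rotation."""
    return Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis)).apply(v)


class TestHingeAxis:
    @pytest.mark.parametrize(
        "spoi, expected",
        [
            (0.0, (0.0, 1.0, 0.0)),
            (10.0, (0.0, np.cos(np.radians(10)), np.sin(np.radians(10)))),
            (-10.0, (0.0, np.cos(np.radians(10)), -np.sin(np.radians(10)))),
        ],
    )
    def test_true_lateral_direction(self, spoi, expected):
        np.testing.assert_allclose(hinge_axis(spoi), expected, atol=1e-15)

    @pytest.mark.parametrize("spoi", [90.0, -90.0, 120.0])
    def test_out_of_domain_rejected(self, spoi):
        with pytest.raises(InvalidPlanError):
            hinge_axis(spoi)

    @given(spoi=st.floats(-89.9, 89.9))
    @settings(deadline=None, derandomize=True)
    def test_unit_and_lateral_free(self, spoi):
        a = hinge_axis(spoi)
        assert a[0] == 0.0
        assert abs(np.linalg.norm(a) - 1.0) < 1e-12


class TestRotateAboutAxis:
    def test_zero_angle_is_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(rotate_about_axis(v, [0, 0, 1], 0.0), v)

    def test_axis_is_fixed_point(self):
        a = hinge_axis(17.0)
        np.testing.assert_allclose(rotate_about_axis(3.0 * a, a, 123.4), 3.0 * a, atol=1e-12)

    def test_quarter_turn_sign(self):
        # right-handed about +y: +z goes to +x
        out = rotate_about_axis([0, 0, 1], [0, 1, 0], 90.0)
        np.testing.assert_allclose(out, [1, 0, 0], atol=1e-12)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            rotate_about_axis([1, 0, 0], [0, 0, 2], 10.0)

    @given(
        v=st.tuples(*[st.floats(-10, 10)] * 3),
        spoi=st.floats(-80, 80),
        angle=st.floats(-180, 180),
    )
    @settings(deadline=None, derandomize=True)
    def test_matches_scipy_and_preserves_length(self, v, spoi, angle):
        v = np.array(v)
        a = hinge_axis(spoi)
        out = rotate_about_axis(v, a, angle)
        np.testing.assert_allclose(out, scipy_rotate(v, a, angle), atol=1e-9)
        assert abs(np.linalg.norm(out) - np.linalg.norm(v)) < 1e-10


class TestSlopeMeasurement:
    def test_definition_examples(self):
        r = np.radians(10.0)
        assert sagittal_slope_angle([0.0, np.cos(r), np.sin(r)]) == pytest.approx(10.0)
        assert sagittal_slope_angle([0.0, 1.0, 0.0]) == 0.0

    def test_medial_component_ignored(self, rng):
        d = np.array([0.7, np.cos(np.radians(8)), np.sin(np.radians(8))])
        assert sagittal_slope_angle(d) == pytest.approx(8.0)

    def test_degenerate_direction_rejected(self):
        with pytest.raises(DegenerateDirectionError):
            sagittal_slope_angle([1.0, 0.0, 0.5])


class TestOpenedSlopeDirection:
    def test_zero_correction_unchanged(self):
        plan = OsteotomyPlan(spoi=20.0, correction=0.0)
        r = np.radians(10.0)
        np.testing.assert_allclose(
            opened_slope_direction(10.0, plan), [0.0, np.cos(r), np.sin(r)], atol=1e-12
        )

    @pytest.mark.parametrize("theta", [0.0, 10.0, 30.0])
    def test_parallel_cut_preserves_direction(self, theta):
        plan = OsteotomyPlan(spoi=10.0, correction=theta)
        r = np.radians(10.0)
        np.testing.assert_allclose(
            opened_slope_direction(10.0, plan), [0.0, np.cos(r), np.sin(r)], atol=1e-12
        )

    def test_posterior_inclined_30deg_correction(self):
        plan = OsteotomyPlan(spoi=20.0, correction=30.0)
        slope = sagittal_slope_angle(opened_slope_direction(10.0, plan))
        assert round(slope, 1) == 11.3


class TestClosedForm:
    @pytest.mark.parametrize("theta", np.arange(0.0, 31.0, 5.0))
    @pytest.mark.parametrize("alpha0", [-5.0, 10.0, 25.0])
    def test_parallel_invariance_exact(self, alpha0, theta):
        assert closed_form_pts(alpha0, alpha0, theta) == pytest.approx(alpha0, abs=1e-12)

    @given(alpha0=angles, spoi=angles)
    @settings(deadline=None, derandomize=True)
    def test_identity_at_zero_correction(self, alpha0, spoi):
        assert closed_form_pts(alpha0, spoi, 0.0) == pytest.approx(alpha0, abs=1e-12)

    @pytest.mark.parametrize(
        "spoi, theta, expected",
        [(-10.0, 20.0, 8.9), (20.0, 25.0, 10.9), (0.0, 30.0, 8.7)],
    )
    def test_published_cells(self, spoi, theta, expected):
        assert round(closed_form_pts(10.0, spoi, theta), 1) == expected

    @given(alpha0=angles, spoi=angles, theta=corrections)
    @settings(deadline=None, derandomize=True)
    def test_agrees_with_rotation_pipeline(self, alpha0, spoi, theta):
        plan = OsteotomyPlan(spoi=spoi, correction=theta)
        pipeline = sagittal_slope_angle(opened_slope_direction(alpha0, plan))
        assert closed_form_pts(alpha0, spoi, theta) == pytest.approx(pipeline, abs=1e-10)

    @given(alpha0=angles, spoi=angles, theta=corrections)
    @settings(deadline=None, derandomize=True)
    def test_rotation_sign_invariance(self, alpha0, spoi, theta):
        a = hinge_axis(spoi)
        r = np.radians(alpha0)
        s = np.array([0.0, np.cos(r), np.sin(r)])
        plus = rotate_about_axis(s, a, theta)
        minus = rotate_about_axis(s, a, -theta)
        np.testing.assert_allclose(plus[1:], minus[1:], atol=1e-12)
        np.testing.assert_allclose(plus[0], -minus[0], atol=1e-12)

    def test_monotone_on_grid(self):
        grid = np.arange(0.0, 31.0, 5.0)
        for spoi, sign in [(20.0, 1), (0.0, -1), (-10.0, -1)]:
            vals = [closed_form_pts(10.0, spoi, t) for t in grid]
            assert np.all(sign * np.diff(vals) > 0)

    def test_small_angle_law(self, rng):
        # (alpha'(theta) - alpha0)/theta^2 -> (1/4) sin(2(spoi - alpha0)) [rad]
        for _ in range(20):
            alpha0, spoi = rng.uniform(-30, 30, 2)
            limit = 0.25 * np.sin(2.0 * np.radians(spoi - alpha0))
            for theta in (0.1, 0.05):
                ratio = np.radians(closed_form_pts(alpha0, spoi, theta) - alpha0)
                ratio /= np.radians(theta) ** 2
                assert ratio == pytest.approx(limit, abs=5e-6)


class TestTransformPoint:
    def test_zero_correction_and_hinge_fixed(self):
        plan = OsteotomyPlan(spoi=5.0, correction=0.0)
        p = np.array([12.0, 3.0, 70.0])
        np.testing.assert_allclose(transform_point(p, plan), p)
        plan = OsteotomyPlan(spoi=5.0, correction=25.0)
        on_hinge = plan.hinge_point() + 7.0 * plan.hinge_direction
        np.testing.assert_allclose(transform_point(on_hinge, plan), on_hinge, atol=1e-12)

    def test_medial_top_edge_elevates(self, column):
        # opening the wedge must raise the medial side of the proximal fragment
        p = np.array([column.width_ml, 25.0, column.top_z(25.0)])
        for spoi in (-10.0, 0.0, 10.0, 20.0):
            plan = OsteotomyPlan(spoi=spoi, correction=10.0)
            assert transform_point(p, plan)[2] > p[2]

    @given(
        spoi=st.floats(-25, 25),
        theta=st.floats(0.1, 30.0),
        p=st.tuples(st.floats(0, 50), st.floats(0, 50), st.floats(55, 95)),
    )
    @settings(deadline=None, derandomize=True)
    def test_matches_direct_rotation_matrix(self, spoi, theta, p):
        plan = OsteotomyPlan(spoi=spoi, correction=theta)
        h = plan.hinge_point()
        expected = h + scipy_rotate(np.array(p) - h, plan.hinge_direction, -theta)
        np.testing.assert_allclose(transform_point(p, plan), expected, atol=1e-9)


def test_slope_independent_of_column_dimensions(rng):
    """The measured slope depends only on the three angles, never on size."""
    from owhto.experiment import digitize_endpoints, measure_slope
    from owhto import NoiseModel

    silent = NoiseModel(sigma_point=0.0, sigma_mount=0.0)
    for _ in range(10):
        w, d, h = rng.uniform(10, 200, 3)
        spoi, theta = rng.uniform(-25, 25), rng.uniform(0, 30)
        col = ColumnModel(width_ml=w, depth_ap=d, height=h + d, alpha0=10.0)
        plan = OsteotomyPlan(spoi=spoi, correction=theta, cut_height=h / 2.0)
        slope = measure_slope(digitize_endpoints(col, plan, silent, rng))
        assert slope == pytest.approx(closed_form_pts(10.0, spoi, theta), abs=1e-9)
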