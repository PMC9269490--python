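import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from reference_impls import fritsch_carlson_eval
from spineposture.errors import InvalidInputError
from spineposture.rotations import (
    EulerZYX,
    RotationQ,
    arc_length,
    euler_from_quat,
    fit_skin_spline,
    pchip_eval,
    quat_from_euler,
    unwrap_angles,
)


def _matrix_zyx(yaw, pitch, roll):
    """Independent matrix-composition oracle Rz(yaw)·Ry(pitch)·Rx(roll)."""
    cz, sz = math.cos(yaw), math.sin(yaw)
    cy, sy = math.cos(pitch), math.sin(pitch)
    cx, sx = math.cos(roll), math.sin(roll)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


class TestQuaternionEuler:
    @pytest.mark.parametrize(
        "euler, expected",
        [
            (EulerZYX(0, 0, 0), (1, 0, 0, 0)),
            (EulerZYX(math.pi, 0, 0), (0, 0, 0, 1)),
        ],
    )
    def test_axis_cases(self, euler, expected):
        q = quat_from_euler(euler)
        assert np.allclose(q.as_array(), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "angles",
        [(30, 20, 10), (45, -30, 60), (-120, 80, -15), (170, -89, 5)],
    )
    def test_matches_matrix_composition_oracle(self, angles):
        yaw, pitch, roll = (math.radians(a) for a in angles)
        q = quat_from_euler(EulerZYX(yaw, pitch, roll))
        assert np.allclose(q.as_matrix(), _matrix_zyx(yaw, pitch, roll), atol=1e-12)

    def test_identity_extraction(self):
        e = euler_from_quat(RotationQ.identity())
        assert e.yaw == e.pitch == e.roll == 0.0
        assert not e.gimbal_lock

    def test_round_trip_over_random_rotations(self):
        rots = Rotation.random(1000, rng=np.random.default_rng(7))
        worst = 0.0
        for r in rots:
            q = RotationQ.from_scipy(r)
            q2 = quat_from_euler(euler_from_quat(q))
            worst = max(worst, q.angle_to(q2))
        assert worst < 1e-9

    def test_pitch_range_on_extraction(self):
        rots = Rotation.random(200, rng=np.random.default_rng(3))
        for r in rots:
            e = euler_from_quat(RotationQ.from_scipy(r))
            assert -math.pi / 2 <= e.pitch <= math.pi / 2
            assert -math.pi < e.yaw <= math.pi + 1e-15
            assert -math.pi < e.roll <= math.pi + 1e-15

    def test_gimbal_lock_flagged_with_yaw_zeroed(self):
        q = quat_from_euler(EulerZYX(0.3, math.pi / 2, 0.1))
        e = euler_from_quat(q)
        assert e.gimbal_lock
        assert e.yaw == 0.0
        assert e.pitch == pytest.approx(math.pi / 2, abs=1e-9)
        # the flagged triplet still reproduces the same rotation
        assert q.angle_to(quat_from_euler(e)) < 1e-9

    @given(st.floats(-math.pi, math.pi), st.floats(-1.4, 1.4), st.floats(-math.pi, math.pi))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, yaw, pitch, roll):
        q = quat_from_euler(EulerZYX(yaw, pitch, roll))
        assert q.angle_to(quat_from_euler(euler_from_quat(q))) < 1e-9

    def test_unit_norm_invariant_after_composition(self):
        q = quat_from_euler(EulerZYX(1.0, 0.5, -0.3))
        p = q * q.inverse()
        assert abs(sum(c * c for c in p.as_array()) - 1) < 1e-9
        assert p.angle_to(RotationQ.identity()) < 1e-9

    def test_canonical_double_cover(self):
        q = RotationQ(-0.5, 0.5, 0.5, 0.5)
        assert q.w >= 0


class TestUnwrap:
    def test_single_wrap(self):
        out = np.degrees(unwrap_angles(np.radians([170, 175, -175])))
        assert np.allclose(out, [170, 175, 185], atol=1e-9)

    def test_monotone_series_unchanged(self):
        series = np.radians([-90, -30, 10, 80, 170])
        assert np.allclose(unwrap_angles(series), series)

    def test_minimal_jump(self):
        out = np.degrees(unwrap_angles(np.radians([-179, 179, -179])))
        assert np.allclose(out, [-179, -181, -179], atol=1e-9)

    def test_successive_differences_bounded(self, rng):
        series = rng.uniform(-math.pi, math.pi, size=50)
        diffs = np.diff(unwrap_angles(series))
        assert np.all(diffs > -math.pi - 1e-12)
        assert np.all(diffs <= math.pi + 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            unwrap_angles([])


class TestPchip:
    def test_knots_reproduced_exactly(self):
        x = [0.0, 1.0, 2.5, 4.0]
        y = [1.0, -2.0, 0.5, 3.0]
        assert np.allclose(pchip_eval(x, y, x), y, atol=0)

    def test_linear_data_reproduced(self):
        x = np.arange(5.0)
        y = 2.0 * x - 3.0
        q = np.linspace(0, 4, 33)
        assert np.allclose(pchip_eval(x, y, q), 2.0 * q - 3.0, atol=1e-12)

    def test_monotone_no_overshoot_and_matches_reference(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 8.0, 9.0])
        q = np.array([1.5, 2.5, 3.5])
        vals = pchip_eval(x, y, q)
        assert np.all(vals >= [1, 2, 8]) and np.all(vals <= [2, 8, 9])
        assert np.allclose(vals, fritsch_carlson_eval(x, y, q), atol=1e-12)

    def test_matches_reference_on_random_monotone_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            x = np.cumsum(rng.uniform(0.2, 2.0, size=n))
            y = np.cumsum(rng.uniform(-1.0, 2.0, size=n))
            q = rng.uniform(x[0], x[-1], size=40)
            assert np.allclose(
                pchip_eval(x, y, q), fritsch_carlson_eval(x, y, q), atol=1e-12
            )

    @pytest.mark.parametrize(
        "x, y",
        [([1.0], [1.0]), ([1.0, 1.0, 2.0], [0.0, 1.0, 2.0]), ([2.0, 1.0], [0.0, 1.0])],
    )
    def test_invalid_knots_rejected(self, x, y):
        with pytest.raises(InvalidInputError):
            pchip_eval(x, y, [1.0])


class TestSkinSpline:
    def test_collinear_points_give_straight_segment(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [3, 3, 3]], dtype=float)
        s = fit_skin_spline(pts)
        assert arc_length(s) == pytest.approx(math.sqrt(27), rel=1e-9)
        mid = s.position(0.5 * sum(s.domain))
        assert np.allclose(np.cross(mid - pts[0], pts[2] - pts[0]), 0, atol=1e-9)

    def test_knots_reproduced(self, rng):
        pts = rng.normal(size=(8, 3))
        s = fit_skin_spline(pts)
        assert np.allclose(s.position(s.t), pts, atol=1e-12)

    def test_circle_arc_length_matches_analytic(self):
        r = 7.0
        theta = np.linspace(0, np.pi, 100)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)], axis=1)
        s = fit_skin_spline(pts)
        assert arc_length(s) == pytest.approx(np.pi * r, rel=1e-3)

    def test_helix_arc_length_matches_analytic(self):
        a, b = 3.0, 0.5
        t = np.linspace(0, 4 * np.pi, 200)
        pts = np.stack([a * np.cos(t), a * np.sin(t), b * t], axis=1)
        s = fit_skin_spline(pts)
        expected = 4 * np.pi * math.hypot(a, b)
        assert arc_length(s) == pytest.approx(expected, rel=1e-3)

    def test_arc_length_additive(self, rng):
        pts = np.cumsum(rng.uniform(0.1, 1.0, size=(10, 3)), axis=0)
        s = fit_skin_spline(pts)
        lo, hi = s.domain
        a, b, c = lo + 0.1, 0.5 * (lo + hi), hi - 0.2
        assert arc_length(s, a, c) == pytest.approx(
            arc_length(s, a, b) + arc_length(s, b, c), rel=1e-6
        )

    def test_zero_length_and_domain_checks(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]], dtype=float)
        s = fit_skin_spline(pts)
        assert arc_length(s, 1.0, 1.0) == 0.0
        with pytest.raises(InvalidInputError):
            arc_length(s, -1.0, 1.0)
        with pytest.raises(InvalidInputError):
            arc_length(s, 1.0, 0.5)

    def test_duplicate_consecutive_points_rejected(self):
        pts = [[0, 0, 0], [0, 0, 0], [0, 0, 1]]
        with pytest.raises(InvalidInputError):
            fit_skin_spline(pts)
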