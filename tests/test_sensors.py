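import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from reference_impls import kabsch_svd
from spineposture.errors import InvalidInputError
from spineposture.rotations import EulerZYX, RotationQ, euler_from_quat, quat_from_euler
from spineposture.sensors import (
    MarkerCluster,
    SensorReading,
    apply_corrections,
    average_quaternions,
    cluster_pose,
    estimate_plate_offsets,
    madgwick_step,
    normalize_heading,
    time_average_readings,
)

TEMPLATE = np.array([[25.0, 15.0, 20.0], [-25.0, 15.0, 20.0], [0.0, -18.0, 20.0]])
SENSORS = ["L5", "L1", "T10", "T7", "T4", "T1"]


def _random_rotation(rng):
    return RotationQ.from_scipy(Rotation.random(rng=rng))


class TestPlateCalibration:
    def test_identical_windows_give_identity_corrections(self):
        q = quat_from_euler(EulerZYX(0.4, 0.2, -0.1))
        cal = estimate_plate_offsets({s: [q] * 12 for s in SENSORS})
        for c in cal.corrections.values():
            assert c.angle_to(RotationQ.identity()) < 1e-12

    def test_constructed_bias_recovered(self):
        q = RotationQ.identity()
        bias = RotationQ.about_z(math.radians(5.0))
        windows = {s: [q] * 10 for s in SENSORS}
        windows["T7"] = [bias * q] * 10
        cal = estimate_plate_offsets(windows, reference="L5")
        expected = RotationQ.about_z(math.radians(-5.0))
        assert cal.corrections["T7"].angle_to(expected) < 1e-9
        assert cal.corrections["L5"].angle_to(RotationQ.identity()) < 1e-12

    def test_noiseless_recovery_below_hundredth_degree(self, rng):
        plate = _random_rotation(rng)
        biases = {s: _random_rotation(rng) for s in SENSORS}
        biases["L5"] = RotationQ.identity()
        windows = {s: [biases[s] * plate] * 10 for s in SENSORS}
        cal = estimate_plate_offsets(windows, reference="L5")
        for s in SENSORS:
            err = cal.corrections[s].angle_to(biases[s].inverse())
            assert math.degrees(err) < 0.01

    def test_noisy_recovery_monte_carlo(self, rng):
        """Bias recovery relative to the reference sensor under window noise.

        The reference sensor's own noise enters every correction as a
        common rotation that downstream heading cancellation removes, so
        recovery is judged on correction∘bias relative to the reference's.
        """
        plate = RotationQ.identity()
        biases = {s: RotationQ.about_z(math.radians(rng.uniform(-10, 10))) for s in SENSORS}
        biases["L5"] = RotationQ.identity()
        windows = {}
        for s in SENSORS:
            qs = []
            for _ in range(100):
                noise = quat_from_euler(EulerZYX(*np.radians(rng.normal(0, 0.2, 3))))
                qs.append(noise * biases[s] * plate)
            windows[s] = qs
        cal = estimate_plate_offsets(windows, reference="L5")
        residual_ref = cal.corrections["L5"] * biases["L5"]
        errs = [
            math.degrees((cal.corrections[s] * biases[s]).angle_to(residual_ref))
            for s in SENSORS
        ]
        assert np.mean(errs) < 0.05
        assert max(errs) < 0.1

    def test_missing_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_plate_offsets({"T1": [RotationQ.identity()]}, reference="L5")


class TestApplyCorrections:
    def test_bias_round_trip(self, rng):
        truth = {s: _random_rotation(rng) for s in SENSORS}
        biases = {s: _random_rotation(rng) for s in SENSORS}
        biases["L5"] = RotationQ.identity()
        windows = {s: [biases[s]] * 10 for s in SENSORS}
        cal = estimate_plate_offsets(windows, reference="L5")
        readings = [SensorReading(s, 0.0, biases[s] * truth[s]) for s in SENSORS]
        out = apply_corrections(readings, cal)
        for r in out:
            assert r.orientation.angle_to(truth[r.level]) < 1e-9
            assert abs(np.linalg.norm(r.orientation.as_array()) - 1) < 1e-12

    def test_missing_correction_rejected(self):
        cal = estimate_plate_offsets({"L5": [RotationQ.identity()]}, reference="L5")
        with pytest.raises(InvalidInputError):
            apply_corrections([SensorReading("T1", 0.0, RotationQ.identity())], cal)


class TestHeadingNormalization:
    def _readings(self, rng):
        return [
            SensorReading(s, float(t), _random_rotation(rng))
            for s in SENSORS
            for t in range(3)
        ]

    def test_base_yaw_zeroed(self, rng):
        out = normalize_heading(self._readings(rng), base_level="L5", t0=0.0)
        base0 = [r for r in out if r.level == "L5" and r.time == 0.0][0]
        assert abs(euler_from_quat(base0.orientation).yaw) < 1e-9

    def test_invariance_to_common_heading(self, rng):
        readings = self._readings(rng)
        rz = RotationQ.about_z(math.radians(37))
        rotated = [SensorReading(r.level, r.time, rz * r.orientation) for r in readings]
        out1 = normalize_heading(readings, "L5", t0=0.0)
        out2 = normalize_heading(rotated, "L5", t0=0.0)
        for a, b in zip(out1, out2):
            assert a.orientation.angle_to(b.orientation) < 1e-9

    def test_already_normalized_unchanged(self):
        q = quat_from_euler(EulerZYX(0.0, 0.4, 0.1))  # zero yaw
        readings = [SensorReading("L5", 0.0, q), SensorReading("T1", 0.0, q)]
        out = normalize_heading(readings, "L5")
        for a, b in zip(readings, out):
            assert a.orientation.angle_to(b.orientation) < 1e-12

    def test_missing_base_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_heading([SensorReading("T1", 0.0, RotationQ.identity())], "L5")


class TestQuaternionAveraging:
    def test_double_cover_safe(self):
        q = quat_from_euler(EulerZYX(1.0, 0.2, -0.4))
        flipped = RotationQ(*(-q.as_array()))  # canonicalises back, same rotation
        mean = average_quaternions([q, flipped, q])
        assert mean.angle_to(q) < 1e-12

    def test_time_average_groups_by_level(self, rng):
        q1, q2 = _random_rotation(rng), _random_rotation(rng)
        readings = [
            SensorReading("L5", 0.0, q1),
            SensorReading("L5", 0.01, q1),
            SensorReading("T1", 0.0, q2),
        ]
        means = time_average_readings(readings)
        assert means["L5"].angle_to(q1) < 1e-12
        assert means["T1"].angle_to(q2) < 1e-12


class TestClusterPose:
    def test_template_observation_identity(self):
        c = MarkerCluster(TEMPLATE.copy(), TEMPLATE.copy(), np.array([1.0, 2.0, 3.0]))
        pose = cluster_pose(c)
        assert pose.rotation.angle_to(RotationQ.identity()) < 1e-12
        assert np.allclose(pose.sensor_position, [1, 2, 3], atol=1e-12)
        assert pose.rms_residual < 1e-12

    def test_exact_rigid_motion_recovered(self, rng):
        R = _random_rotation(rng)
        t = rng.normal(0, 100, 3)
        c = MarkerCluster(R.apply(TEMPLATE) + t, TEMPLATE.copy(), np.array([5.0, -3.0, 2.0]))
        pose = cluster_pose(c)
        assert pose.rotation.angle_to(R) < 1e-9
        assert np.allclose(pose.sensor_position, R.apply([5.0, -3.0, 2.0]) + t, atol=1e-9)

    def test_matches_svd_oracle_over_random_rigid_motions(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(1000):
            R = Rotation.random(rng=rng)
            t = rng.normal(0, 50, 3)
            obs = R.apply(TEMPLATE) + t
            pose = cluster_pose(MarkerCluster(obs, TEMPLATE.copy(), np.zeros(3)))
            R_ref, t_ref = kabsch_svd(TEMPLATE, obs)
            dev = Rotation.from_matrix(R_ref).inv() * pose.rotation.as_scipy()
            worst = max(worst, float(dev.magnitude()),
                        float(np.abs(pose.sensor_position - t_ref).max()))
        assert worst < 1e-9

    def test_noisy_markers_seeded(self, rng):
        """0.5 mm marker noise on the ~5 cm housing footprint.

        With three markers at ~25 mm lever arms the attainable attitude
        precision is ~1.2 deg at this noise level (position stays well
        below 1 mm); the noisy fit must still agree with the independent
        SVD solution exactly — the noise limits physics, not the solver.
        """
        R = _random_rotation(rng)
        t = np.array([100.0, -50.0, 30.0])
        errs_rot, errs_pos = [], []
        for _ in range(50):
            obs = R.apply(TEMPLATE) + t + rng.normal(0, 0.5, TEMPLATE.shape)
            pose = cluster_pose(MarkerCluster(obs, TEMPLATE.copy(), np.zeros(3)))
            R_ref, t_ref = kabsch_svd(TEMPLATE, obs)
            assert float(
                (Rotation.from_matrix(R_ref).inv() * pose.rotation.as_scipy()).magnitude()
            ) < 1e-9
            errs_rot.append(math.degrees(pose.rotation.angle_to(R)))
            errs_pos.append(np.linalg.norm(pose.sensor_position - t))
        assert np.mean(errs_rot) < 1.5
        assert np.mean(errs_pos) < 1.0

    def test_collinear_markers_rejected(self):
        bad = np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0]])
        with pytest.raises(InvalidInputError):
            MarkerCluster(bad, TEMPLATE.copy(), np.zeros(3))


class TestMadgwick:
    def test_pure_gyro_integration_about_z(self):
        q = RotationQ.identity()
        omega, dt, n = 0.5, 0.01, 200
        for _ in range(n):
            q = madgwick_step(q, (0, 0, omega), (0, 0, 1), None, beta=0.0, dt=dt)
        yaw = euler_from_quat(q).yaw
        assert yaw == pytest.approx(omega * n * dt, abs=1e-3)

    def test_static_convergence_to_true_attitude(self):
        true_q = quat_from_euler(EulerZYX(0.0, math.radians(20), math.radians(-10)))
        g_sensor = true_q.inverse().apply([0.0, 0.0, 1.0])
        m_sensor = true_q.inverse().apply([0.6, 0.0, -0.8])
        q = RotationQ.identity()
        for _ in range(1000):  # 10 s at 100 Hz
            q = madgwick_step(q, (0, 0, 0), g_sensor, m_sensor, beta=0.1, dt=0.01)
        e = euler_from_quat(q)
        assert math.degrees(abs(e.pitch - math.radians(20))) < 0.5
        assert math.degrees(abs(e.roll - math.radians(-10))) < 0.5

    def test_output_normalized_every_step(self, rng):
        q = RotationQ.identity()
        for _ in range(100):
            q = madgwick_step(
                q, rng.normal(0, 1, 3), rng.normal(0, 1, 3), rng.normal(0, 1, 3),
                beta=0.2, dt=0.01,
            )
            assert abs(np.linalg.norm(q.as_array()) - 1) < 1e-9

    def test_zero_accel_falls_back_to_gyro(self):
        q = RotationQ.identity()
        q2 = madgwick_step(q, (0, 0, 1.0), (0, 0, 0), (1, 0, 0), beta=0.5, dt=0.01)
        assert euler_from_quat(q2).yaw == pytest.approx(0.01, abs=1e-6)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(InvalidInputError):
            madgwick_step(RotationQ.identity(), (0, 0, 0), (0, 0, 1), None, dt=0.0)
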