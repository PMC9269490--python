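"""Sensor-side processing: calibration, heading, marker clusters, fusion.

Turns raw orientation sources — IMU quaternions, raw 9-axis IMU streams
(through a Madgwick MARG step) or 3-marker optical clusters — into
mutually consistent, heading-normalised sensor orientations ready for the
posture pipeline.

Skin-mounted IMUs nominally share one Earth-fixed frame, but per-sensor
errors in sensing gravity and magnetic North leave constant relative
offsets between them.  These are estimated once from a static window with
all sensors co-mounted on a rigid calibration plate and subtracted
thereafter.  The residual common heading is removed by cancelling the
initial vertical-axis (yaw) rotation of the base sensor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError
from .rotations import RotationQ, euler_from_quat

__all__ = [
    "SensorReading",
    "MarkerCluster",
    "CalibrationSet",
    "ClusterPose",
    "average_quaternions",
    "estimate_plate_offsets",
    "apply_corrections",
    "normalize_heading",
    "time_average_readings",
    "cluster_pose",
    "madgwick_step",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensorReading:
    """One orientation sample of the sensor at a vertebral level."""

    level: str
    time: float
    orientation: RotationQ


@dataclass(frozen=True)
class MarkerCluster:
    """Three optical markers rigidly fixed to one sensor (all mm).

    ``template`` holds the same three markers in the sensor's local frame;
    ``sensor_point_local`` is the point on the sensor whose global position
    the cluster is used to recover.
    """

    markers: np.ndarray
    template: np.ndarray
    sensor_point_local: np.ndarray
    level: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.markers, dtype=float)
        t = np.asarray(self.template, dtype=float)
        p = np.asarray(self.sensor_point_local, dtype=float)
        if m.shape != (3, 3) or t.shape != (3, 3) or p.shape != (3,):
            raise InvalidInputError("cluster needs 3 markers, 3 template points, 1 sensor point")
        for name, pts in (("markers", m), ("template", t)):
            area = 0.5 * np.linalg.norm(
                np.cross(pts[1] - pts[0], pts[2] - pts[0])
            )
            if area <= 1.0:  # mm^2
                raise InvalidInputError(f"{name} are (near-)collinear (area {area:.3g} mm^2)")
        object.__setattr__(self, "markers", m)
        object.__setattr__(self, "template", t)
        object.__setattr__(self, "sensor_point_local", p)


@dataclass(frozen=True)
class CalibrationSet:
    """Per-sensor constant correction quaternions from a plate capture."""

    corrections: Mapping[str, RotationQ]
    reference: str
    spreads_deg: Mapping[str, float] = field(default_factory=dict, compare=False)


class ClusterPose(NamedTuple):
    rotation: RotationQ
    sensor_position: np.ndarray
    rms_residual: float


def average_quaternions(qs: Sequence[RotationQ]) -> RotationQ:
    """Mean orientation as the principal eigenvector of sum(q q^T).

    Robust to the quaternion double cover (q and -q accumulate identically).
    """
    if len(qs) == 0:
        raise InvalidInputError("cannot average an empty set of quaternions")
    A = np.zeros((4, 4))
    for q in qs:
        v = q.as_array()
        A += np.outer(v, v)
    w, v = np.linalg.eigh(A)
    if w[-1] < 1e-12:
        raise InvalidInputError("degenerate quaternion average")
    q = v[:, -1]
    return RotationQ(*q)


def estimate_plate_offsets(
    static_windows: Mapping[str, Sequence[RotationQ]],
    reference: str = "L5",
    spread_warn_deg: float = 2.0,
) -> CalibrationSet:
    """Per-sensor corrections from a static co-mounted (plate) capture.

    With all sensors rigidly mounted in a nominally identical orientation,
    each sensor's window mean qbar_i is computed and the correction
    qbar_ref * qbar_i^-1 maps sensor i's frame onto the reference
    sensor's.  Corrections are constant afterwards (one plate capture is
    valid for a whole day of measurements).
    """
    if reference not in static_windows:
        raise InvalidInputError(f"reference sensor {reference!r} not in plate capture")
    means: dict[str, RotationQ] = {}
    spreads: dict[str, float] = {}
    for sensor, window in static_windows.items():
        if len(window) < 1:
            raise InvalidInputError(f"empty plate window for sensor {sensor!r}")
        mean = average_quaternions(window)
        means[sensor] = mean
        spread = max(mean.angle_to(q) for q in window)
        spreads[sensor] = math.degrees(spread)
        if spreads[sensor] > spread_warn_deg:
            log.warning(
                "plate window for %s spans %.2f deg (> %.1f): plate may have moved",
                sensor, spreads[sensor], spread_warn_deg,
            )
    q_ref = means[reference]
    corrections = {
        sensor: q_ref * mean.inverse() for sensor, mean in means.items()
    }
    return CalibrationSet(corrections=corrections, reference=reference, spreads_deg=spreads)


def apply_corrections(
    readings: Iterable[SensorReading], cal: CalibrationSet
) -> list[SensorReading]:
    """Premultiply each reading by its sensor's plate correction."""
    out = []
    for r in readings:
        try:
            c = cal.corrections[r.level]
        except KeyError:
            raise InvalidInputError(f"no calibration correction for sensor {r.level!r}") from None
        out.append(SensorReading(r.level, r.time, c * r.orientation))
    return out


def normalize_heading(
    readings: Sequence[SensorReading], base_level: str = "L5", t0: float | None = None
) -> list[SensorReading]:
    """Cancel the base sensor's initial yaw for the whole set.

    All orientations are premultiplied by Rz(-psi0) where psi0 is the yaw
    of ``base_level`` at (the sample closest to) ``t0``; afterwards the
    base yaw at t0 is zero and downstream output is invariant to any
    common heading applied to all sensors.
    """
    base = [r for r in readings if r.level == base_level]
    if not base:
        raise InvalidInputError(f"base level {base_level!r} absent from readings")
    if t0 is None:
        ref = min(base, key=lambda r: r.time)
    else:
        ref = min(base, key=lambda r: abs(r.time - t0))
    psi0 = euler_from_quat(ref.orientation).yaw
    rz = RotationQ.about_z(-psi0)
    return [SensorReading(r.level, r.time, rz * r.orientation) for r in readings]


def time_average_readings(
    readings: Iterable[SensorReading],
) -> dict[str, RotationQ]:
    """Per-level mean orientation over a static capture window."""
    grouped: dict[str, list[RotationQ]] = {}
    for r in readings:
        grouped.setdefault(r.level, []).append(r.orientation)
    return {lvl: average_quaternions(qs) for lvl, qs in grouped.items()}


def cluster_pose(obs: MarkerCluster, residual_warn_mm: float = 2.0) -> ClusterPose:
    """Rigid pose of a sensor from its 3-marker cluster (least squares).

    Fits the local template to the observed markers (Kabsch), returning
    the sensor->global rotation, the global position of the sensor point,
    and the RMS fitting residual in mm.
    """
    obs_c = obs.markers - obs.markers.mean(axis=0)
    tmpl_c = obs.template - obs.template.mean(axis=0)
    rot, rssd = Rotation.align_vectors(obs_c, tmpl_c)
    rms = float(rssd) / math.sqrt(3.0)
    if rms > residual_warn_mm:
        log.warning(
            "cluster fit residual %.2f mm (> %.1f): possible marker swap or occlusion",
            rms, residual_warn_mm,
        )
    q = RotationQ.from_scipy(rot)
    t = obs.markers.mean(axis=0) - rot.apply(obs.template.mean(axis=0))
    position = rot.apply(obs.sensor_point_local) + t
    return ClusterPose(q, position, rms)


def madgwick_step(
    q: RotationQ,
    gyro: Sequence[float],
    accel: Sequence[float],
    mag: Sequence[float] | None,
    beta: float = 0.1,
    dt: float = 0.01,
) -> RotationQ:
    """One gradient-descent MARG fusion update (gain ``beta``, 1/s).

    Integrates the gyroscope quaternion derivative and subtracts a
    beta-weighted normalised gradient of the accelerometer(+magnetometer)
    alignment objective.  ``q`` is the sensor->Earth orientation.  A zero
    accelerometer norm skips the corrective term (gyro-only integration);
    ``mag=None`` runs the IMU-only (gravity) objective.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    w, x, y, z = q.w, q.x, q.y, q.z
    gx, gy, gz = (float(v) for v in gyro)
    # gyro quaternion derivative: 0.5 * q ⊗ (0, omega)
    qdot = 0.5 * np.array(
        [
            -x * gx - y * gy - z * gz,
            w * gx + y * gz - z * gy,
            w * gy - x * gz + z * gx,
            w * gz + x * gy - y * gx,
        ]
    )
    a = np.asarray(accel, dtype=float)
    a_norm = np.linalg.norm(a)
    if a_norm > 1e-12 and beta > 0:
        a = a / a_norm
        # gravity objective: R(q)^T (0,0,1) - a_hat
        f_g = np.array(
            [
                2 * (x * z - w * y) - a[0],
                2 * (y * z + w * x) - a[1],
                1 - 2 * (x * x + y * y) - a[2],
            ]
        )
        J_g = np.array(
            [
                [-2 * y, 2 * z, -2 * w, 2 * x],
                [2 * x, 2 * w, 2 * z, 2 * y],
                [0.0, -4 * x, -4 * y, 0.0],
            ]
        )
        grad = J_g.T @ f_g
        m = None if mag is None else np.asarray(mag, dtype=float)
        if m is not None and np.linalg.norm(m) > 1e-12:
            m = m / np.linalg.norm(m)
            # Earth-frame field from the current estimate, flattened to (bx, 0, bz)
            h = q.apply(m)
            bx = math.hypot(h[0], h[1])
            bz = h[2]
            f_b = np.array(
                [
                    bx * (1 - 2 * y * y - 2 * z * z) + 2 * bz * (x * z - w * y) - m[0],
                    2 * bx * (x * y - w * z) + 2 * bz * (y * z + w * x) - m[1],
                    2 * bx * (x * z + w * y) + bz * (1 - 2 * x * x - 2 * y * y) - m[2],
                ]
            )
            J_b = np.array(
                [
                    [-2 * bz * y, 2 * bz * z, -4 * bx * y - 2 * bz * w, -4 * bx * z + 2 * bz * x],
                    [-2 * bx * z + 2 * bz * x, 2 * bx * y + 2 * bz * w, 2 * bx * x + 2 * bz * z, -2 * bx * w + 2 * bz * y],
                    [2 * bx * y, 2 * bx * z - 4 * bz * x, 2 * bx * w - 4 * bz * y, 2 * bx * x],
                ]
            )
            grad = grad + J_b.T @ f_b
        gnorm = np.linalg.norm(grad)
        if gnorm > 1e-12:
            qdot = qdot - beta * grad / gnorm
    q_new = np.array([w, x, y, z]) + qdot * dt
    return RotationQ(*q_new)


def fuse_imu_stream(
    times: Sequence[float],
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray | None,
    beta: float = 0.1,
    q0: RotationQ | None = None,
    warmup: int = 100,
) -> list[RotationQ]:
    """Run ``madgwick_step`` over a raw stream; repeats the first sample
    ``warmup`` times so the estimate settles before t0."""
    q = q0 or RotationQ.identity()
    out: list[RotationQ] = []
    dt0 = float(times[1] - times[0]) if len(times) > 1 else 0.01
    for _ in range(warmup):
        q = madgwick_step(q, (0, 0, 0), accel[0], None if mag is None else mag[0], beta=1.0, dt=dt0)
    prev_t = times[0] - dt0
    for i, t in enumerate(times):
        dt = float(t - prev_t)
        prev_t = float(t)
        q = madgwick_step(q, gyro[i], accel[i], None if mag is None else mag[i], beta=beta, dt=dt)
        out.append(q)
    return out
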