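"""Synthetic standing captures with the statistical structure the method assumes.

Generates ground-truth spines with physiological sagittal curvature —
a lordotic lumbar region, a shallow thoracolumbar-junction dip and an
S-shaped kyphotic thoracic rise, pinned at six anatomical landmarks and
completed by the same shape-preserving cubic the estimator assumes
("spinal curvature is soft") — plus the observations a real session
would produce: skin-mounted sensor orientations carrying the
self-consistent skin-to-vertebra sagittal offsets, per-sensor heading
biases, orientation noise, calibration-plate windows and 3-marker
optical clusters.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .model import (
    LEVELS,
    SpineModel,
    SpinePosture,
    build_default_model,
    forward_kinematics,
    level_index,
    scale_model,
)
from .pipeline import ANTEVERSION_DEG, SubjectParams, _segment_vector
from .rotations import EulerZYX, RotationQ, pchip_eval, quat_from_euler
from .sensors import MarkerCluster, SensorReading

__all__ = [
    "DEFAULT_MARKER_TEMPLATE",
    "DEFAULT_SENSOR_LEVELS",
    "SyntheticSubject",
    "SpineTruth",
    "generate_truth",
    "naive_skin_offsets",
    "skin_sensor_offsets",
    "skin_sensor_orientations",
    "simulate_readings",
    "simulate_plate_windows",
    "simulate_markers",
    "make_cohort",
]

DEFAULT_SENSOR_LEVELS: tuple[str, ...] = ("L5", "L1", "T10", "T7", "T4", "T1")

#: Synthetic 3-marker footprint on a small IMU housing, sensor-local mm.
#: A constructed stand-in for a manufacturer drawing, not measured hardware.
DEFAULT_MARKER_TEMPLATE = np.array(
    [[25.0, 15.0, 20.0], [-25.0, 15.0, 20.0], [0.0, -18.0, 20.0]]
)


@dataclass(frozen=True)
class SyntheticSubject:
    """Parameters of one simulated subject.

    Curvature totals are the summed relative pitch increments over the
    lumbar (lordosis) and thoracic (kyphosis) regions, in degrees;
    ``junction_dip_deg`` is how far the sagittal pitch drops below L1's
    at the thoracolumbar junction (bottoming at T10);
    ``base_pitch_deg`` is the anterior inclination of L5 (its sagittal
    tilt including the pelvic contribution).  ``skin_distance_cm``, when
    given, fixes the subject's stature: the model is scaled so the truth
    T1-L5 skin arc equals it (the value doubles as the tape measurement).
    """

    sex: str = "male"
    lordosis_deg: float = 45.0
    kyphosis_deg: float = 40.0
    junction_dip_deg: float = 3.0
    base_pitch_deg: float = 20.0
    axial_rotation_deg: float = 3.0
    lateral_bend_deg: float = 3.0
    stature_scale: float = 1.0
    skin_distance_cm: float | None = None
    orientation_noise_deg: float = 0.0
    heading_bias_deg: Mapping[str, float] = field(default_factory=dict)
    marker_noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ANTEVERSION_DEG:
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0 <= self.lordosis_deg <= 80 and 0 <= self.kyphosis_deg <= 80):
            raise InvalidInputError("curvature totals must lie in [0, 80] deg")
        if not 0 <= self.junction_dip_deg <= 10:
            raise InvalidInputError("junction dip must lie in [0, 10] deg")
        if self.stature_scale <= 0:
            raise InvalidInputError("stature scale must be positive")
        if self.skin_distance_cm is not None and not self.skin_distance_cm > 0:
            raise InvalidInputError("skin distance must be positive")


@dataclass(frozen=True)
class SpineTruth:
    """Ground truth for one subject: scaled model, posture, per-level Eulers."""

    model: SpineModel
    posture: SpinePosture
    eulers: tuple[EulerZYX, ...]
    subject: SyntheticSubject
    _offset_cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def skin_distance_cm(self) -> float:
        """The tape measurement a session would record (truth arc length)."""
        return self.posture.skin_arc_length_T1_L5

    def subject_params(
        self, sensor_levels: Sequence[str] = DEFAULT_SENSOR_LEVELS
    ) -> SubjectParams:
        return SubjectParams(
            sex=self.subject.sex,
            skin_distance_T1_L5=self.skin_distance_cm,
            sensor_levels=tuple(sensor_levels),
        )


#: Anatomical landmark levels anchoring the sagittal profile (vertebra
#: index 1..17): base, thoracolumbar junction, and the palpable levels
#: conventionally instrumented between them.
_LANDMARK_IDX = np.array([1.0, 5.0, 8.0, 11.0, 14.0, 17.0])


#: Fractions of the thoracic rise reached at T7 and T4: an S-shaped rise
#: with peak slope around the kyphotic apex (T7-T8), tapering toward T1.
_THORACIC_RISE_FRACTIONS = (0.33, 0.72)


def _truth_pitch(subject: SyntheticSubject) -> np.ndarray:
    """Sagittal pitch profile over vertebra index, radians.

    The profile is pinned at six anatomical landmarks: the base
    inclination at L5; L5 minus the lordosis at L1 (so the lumbar pitch
    increments sum to exactly the stated lordosis); a shallow junction
    dip below L1, bottoming at T10, where normal sagittal alignment is
    most reclined; then an S-shaped kyphotic rise through T7 and T4
    ending at L1's pitch plus the stated kyphosis at T1.  The
    per-vertebra pitch is the shape-preserving cubic completion through
    these landmarks — the soft-curvature class the method itself assumes
    ("spinal curvature can be approximated by a cubic spline").
    """
    p0 = math.radians(subject.base_pitch_deg)
    lord = math.radians(subject.lordosis_deg)
    kyph = math.radians(subject.kyphosis_deg)
    dip = math.radians(subject.junction_dip_deg)
    p_l1 = p0 - lord
    p_t10 = p_l1 - dip
    rise = kyph + dip  # T10 -> T1
    f1, f2 = _THORACIC_RISE_FRACTIONS
    landmark_pitch = np.array(
        [p0, p_l1, p_t10, p_t10 + f1 * rise, p_t10 + f2 * rise, p_t10 + rise]
    )
    return pchip_eval(_LANDMARK_IDX, landmark_pitch, np.arange(1.0, 18.0))


def _truth_eulers(subject: SyntheticSubject) -> list[EulerZYX]:
    """Sagittal two-lobe pitch plus low-amplitude smooth yaw/roll."""
    pitch = _truth_pitch(subject)
    i = np.arange(17)
    yaw = math.radians(subject.axial_rotation_deg) * np.sin(math.pi * i / 16)
    roll = math.radians(subject.lateral_bend_deg) * np.sin(2 * math.pi * i / 16)
    return [EulerZYX(yaw[k], pitch[k], roll[k]) for k in range(17)]


def generate_truth(subject: SyntheticSubject) -> SpineTruth:
    """Ground-truth model and posture for a synthetic subject.

    Zero curvature gives a straight vertical chain.  If the subject
    specifies a skin distance, the model scale is solved so the truth
    T1-L5 skin arc equals it exactly.
    """
    eulers = _truth_eulers(subject)
    quats = [quat_from_euler(e) for e in eulers]
    model = scale_model(build_default_model(), subject.stature_scale)
    posture = forward_kinematics(model, quats)
    if subject.skin_distance_cm is not None:
        model = scale_model(
            model, model.scale * subject.skin_distance_cm / posture.skin_arc_length_T1_L5
        )
        posture = forward_kinematics(model, quats)
    return SpineTruth(model=model, posture=posture, eulers=tuple(eulers), subject=subject)


def naive_skin_offsets(truth: SpineTruth, levels: Sequence[str]) -> dict[str, float]:
    """Sagittal angle of each truth skin-surface segment in its vertebra frame."""
    out = {}
    for lvl in levels:
        q_v = truth.posture.orientations[level_index(lvl)]
        v_local = q_v.inverse().apply(_segment_vector(truth.posture, lvl))
        out[lvl] = math.atan2(v_local[0], v_local[2])
    return out


def skin_sensor_offsets(
    truth: SpineTruth, levels: Sequence[str] = DEFAULT_SENSOR_LEVELS
) -> dict[str, float]:
    """Analytic per-sensor sagittal offsets consistent with the skin geometry.

    A skin-mounted sensor reads the vertebral orientation rotated
    sagittally by the local skin-to-vertebra angle.  The skin-segment
    direction itself depends on the orientations of the neighbouring
    vertebrae, so the offsets implied by the model geometry are defined
    self-consistently: the offset set ``delta`` solves

        delta = offsets_measured_on(posture(interpolate(truth + delta)))

    i.e. posing the chain with the sensor (offset-composed) angles and
    measuring the skin-segment angles back returns the same offsets.
    Solved by Newton iteration from the truth-geometry segment angles;
    this is the configuration in which an angular-offset estimation pass
    recovers the composed offsets exactly.

    The base (L5) offset is identically zero: its skin-to-vertebra
    relation is carried by the pelvic-anteversion constant (the sacral
    skin under-reads the L5 inclination by that angle), not by the
    skin-segment geometry, whose lower-lumbar soft-tissue step admits no
    physiological self-consistent segment angle.
    """
    from scipy.optimize import root

    from .pipeline import estimate_angular_offsets, interpolate_vertebral_orientations

    key = tuple(levels)
    if key in truth._offset_cache:
        return dict(truth._offset_cache[key])
    eul = {lvl: truth.eulers[level_index(lvl)] for lvl in levels}
    free = [lvl for lvl in levels if lvl != "L5"]

    def residual(delta: np.ndarray) -> np.ndarray:
        d = dict(zip(free, delta))
        knots = [
            EulerZYX(eul[lvl].yaw, eul[lvl].pitch + d.get(lvl, 0.0), eul[lvl].roll)
            for lvl in levels
        ]
        all17 = interpolate_vertebral_orientations(levels, knots)
        posture = forward_kinematics(
            truth.model, [quat_from_euler(e) for e in all17]
        )
        est = estimate_angular_offsets(posture, free)
        return np.array([est[lvl] for lvl in free]) - delta

    naive = naive_skin_offsets(truth, levels)
    d0 = np.array([naive[lvl] for lvl in free])
    sol = root(residual, d0, method="hybr", tol=1e-12)
    if not sol.success or np.abs(sol.fun).max() > 1e-9:
        raise InvalidInputError(
            "no self-consistent skin-sensor offsets for this subject geometry"
        )
    result = {lvl: 0.0 for lvl in levels}
    result.update(zip(free, (float(d) for d in sol.x)))
    truth._offset_cache[key] = dict(result)
    return result


def skin_sensor_orientations(
    truth: SpineTruth, levels: Sequence[str] = DEFAULT_SENSOR_LEVELS
) -> dict[str, RotationQ]:
    """Noise-free skin-sensor orientations at the instrumented levels.

    Each sensor reports its vertebra's yaw and roll with the
    self-consistent sagittal skin offset added to the pitch.  At L5 the
    sex-specific pelvic anteversion is removed — the skin over the
    sacrum under-measures L5's inclination, which is exactly what the
    estimation pipeline adds back.
    """
    deltas = skin_sensor_offsets(truth, levels)
    antev = math.radians(ANTEVERSION_DEG[truth.subject.sex])
    out: dict[str, RotationQ] = {}
    for lvl in levels:
        e = truth.eulers[level_index(lvl)]
        pitch = e.pitch + deltas[lvl] - (antev if lvl == "L5" else 0.0)
        out[lvl] = quat_from_euler(EulerZYX(e.yaw, pitch, e.roll))
    return out


def _noise_quat(rng: np.random.Generator, sigma_deg: float) -> RotationQ:
    e = np.radians(rng.normal(0.0, sigma_deg, size=3))
    return quat_from_euler(EulerZYX(e[0], e[1], e[2]))


def simulate_readings(
    truth: SpineTruth,
    levels: Sequence[str] = DEFAULT_SENSOR_LEVELS,
    orientation_noise_deg: float | None = None,
    heading_bias_deg: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_samples: int = 1,
    sample_rate: float = 100.0,
) -> list[SensorReading]:
    """Static-capture sensor readings at the instrumented levels.

    Each reading is the analytic skin-sensor orientation, premultiplied by
    the sensor's constant heading bias Rz(bias) (a miscalibrated magnetic
    North) and by a per-sample small random rotation with per-axis sigma
    ``orientation_noise_deg``.  Noise and bias default to the subject's
    own noise spec; with sigma = 0 the output is seed-independent.
    """
    subj = truth.subject
    sigma = subj.orientation_noise_deg if orientation_noise_deg is None else orientation_noise_deg
    biases = subj.heading_bias_deg if heading_bias_deg is None else heading_bias_deg
    rng = np.random.default_rng(subj.seed if seed is None else seed)
    clean = skin_sensor_orientations(truth, levels)
    readings: list[SensorReading] = []
    for lvl in levels:
        bias = RotationQ.about_z(math.radians(biases.get(lvl, 0.0)))
        for k in range(n_samples):
            q = bias * clean[lvl]
            if sigma > 0:
                q = _noise_quat(rng, sigma) * q
            readings.append(SensorReading(lvl, k / sample_rate, q))
    return readings


def simulate_plate_windows(
    levels: Sequence[str] = DEFAULT_SENSOR_LEVELS,
    heading_bias_deg: Mapping[str, float] | None = None,
    plate_orientation: RotationQ | None = None,
    orientation_noise_deg: float = 0.0,
    n_samples: int = 10,
    seed: int = 0,
) -> dict[str, list[RotationQ]]:
    """Co-mounted calibration-plate capture with the same per-sensor biases.

    Every sensor physically shares the plate orientation; each reports it
    through its own heading bias (plus optional noise), so the plate
    calibration can recover and cancel exactly the biases that corrupt
    the on-subject readings.
    """
    biases = heading_bias_deg or {}
    q_p = plate_orientation or RotationQ.identity()
    rng = np.random.default_rng(seed)
    windows: dict[str, list[RotationQ]] = {}
    for lvl in levels:
        bias = RotationQ.about_z(math.radians(biases.get(lvl, 0.0)))
        qs = []
        for _ in range(n_samples):
            q = bias * q_p
            if orientation_noise_deg > 0:
                q = _noise_quat(rng, orientation_noise_deg) * q
            qs.append(q)
        windows[lvl] = qs
    return windows


def simulate_markers(
    truth: SpineTruth,
    levels: Sequence[str] = DEFAULT_SENSOR_LEVELS,
    template: np.ndarray = DEFAULT_MARKER_TEMPLATE,
    marker_noise_mm: float | None = None,
    seed: int | None = None,
) -> dict[str, MarkerCluster]:
    """One static frame of 3-marker clusters, keyed by level (mm).

    Clusters sit at the truth skin points with the skin-sensor
    orientation, providing the optically 'measured' side of a validation:
    cluster_pose on a noiseless cluster returns the truth skin point
    exactly.
    """
    subj = truth.subject
    sigma = subj.marker_noise_mm if marker_noise_mm is None else marker_noise_mm
    rng = np.random.default_rng((subj.seed if seed is None else seed) + 1)
    # markers track the physical housing, so a cluster's pose equals the
    # IMU's noise-free orientation; its position is the truth skin point
    orientations = skin_sensor_orientations(truth, levels)
    out: dict[str, MarkerCluster] = {}
    for lvl in levels:
        i = level_index(lvl)
        q_s = orientations[lvl]
        origin_mm = truth.posture.skin_points[i] * 10.0
        markers = q_s.apply(template) + origin_mm
        if sigma > 0:
            markers = markers + rng.normal(0.0, sigma, size=markers.shape)
        out[lvl] = MarkerCluster(
            markers=markers,
            template=template.copy(),
            sensor_point_local=np.zeros(3),
            level=lvl,
        )
    return out


def make_cohort(
    n: int = 14,
    seed: int = 42,
    orientation_noise_deg: float = 0.0,
    heading_bias_sigma_deg: float = 0.0,
    marker_noise_mm: float = 0.0,
) -> list[SyntheticSubject]:
    """A study cohort: n subjects, balanced sexes, varied anatomy.

    Skin distances are drawn N(43, 4^2) cm truncated to [35, 55];
    curvature totals and the base inclination vary around physiological
    means.  Per-subject seeds derive from the master seed.
    """
    rng = np.random.default_rng(seed)
    cohort: list[SyntheticSubject] = []
    for k in range(n):
        d = float(np.clip(rng.normal(43.0, 4.0), 35.0, 55.0))
        biases = {}
        if heading_bias_sigma_deg > 0:
            biases = {
                lvl: float(rng.normal(0.0, heading_bias_sigma_deg))
                for lvl in DEFAULT_SENSOR_LEVELS
            }
        cohort.append(
            SyntheticSubject(
                sex="male" if k % 2 == 0 else "female",
                lordosis_deg=float(np.clip(rng.normal(45.0, 8.0), 25.0, 70.0)),
                kyphosis_deg=float(np.clip(rng.normal(40.0, 8.0), 25.0, 70.0)),
                junction_dip_deg=float(np.clip(rng.normal(3.0, 1.0), 0.5, 6.0)),
                base_pitch_deg=float(rng.normal(20.0, 4.0)),
                axial_rotation_deg=float(rng.normal(0.0, 2.0)),
                lateral_bend_deg=float(rng.normal(0.0, 2.0)),
                skin_distance_cm=d,
                orientation_noise_deg=orientation_noise_deg,
                heading_bias_deg=biases,
                marker_noise_mm=marker_noise_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cohort
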