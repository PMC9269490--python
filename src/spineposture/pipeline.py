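"""Posture estimation proper: predict, correct and scale the spine.

The method turns a sparse set (4-6) of heading-normalised sensor
orientations into the pose of all 17 thoracolumbar vertebrae:

1. the sensors' yaw/pitch/roll angles — with the sex-specific pelvis
   anteversion added to the L5 pitch — are interpolated over vertebra
   index with a shape-preserving piecewise cubic to all 17 levels, and
   the chain is posed (*predicted* posture);
2. per instrumented level except the base (whose skin-to-vertebra
   correction is the anteversion term itself), the sagittal angular
   offset between the sensor longitudinal axis and the local
   skin-surface segment (caused by spinous processes and soft tissue)
   is measured on the predicted posture;
3. the offsets are subtracted from the sensor pitches, the angles
   re-interpolated and the chain re-posed (*corrected* posture);
4. the model is scaled so that the estimated T1-L5 skin arc length equals
   the tape-measured skin distance, and posed a final time.

Estimated sensor positions are the skin points (optionally the bare
spinous-process tips) of the final posture at the instrumented levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError, PipelineError
from .model import (
    SpineModel,
    SpinePosture,
    forward_kinematics,
    level_index,
    scale_model,
)
from .rotations import EulerZYX, euler_from_quat, pchip_eval, quat_from_euler
from .sensors import (
    CalibrationSet,
    SensorReading,
    apply_corrections,
    normalize_heading,
    time_average_readings,
)

__all__ = [
    "ANTEVERSION_DEG",
    "SubjectParams",
    "TPMResult",
    "interpolate_vertebral_orientations",
    "apply_pelvis_anteversion",
    "estimate_angular_offsets",
    "correct_orientations",
    "compute_scale_factor",
    "run_tpm",
]

log = logging.getLogger(__name__)

#: Additional sagittal rotation of L5 induced by pelvis anteversion, deg.
ANTEVERSION_DEG: dict[str, float] = {"male": 10.0, "female": 14.0}


@dataclass(frozen=True)
class SubjectParams:
    """Subject-specific inputs: sex, tape-measured skin distance, layout."""

    sex: str
    skin_distance_T1_L5: float  # cm, along the skin of the back
    sensor_levels: tuple[str, ...] = ("L5", "L1", "T10", "T7", "T4", "T1")

    def __post_init__(self) -> None:
        if self.sex not in ANTEVERSION_DEG:
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.skin_distance_T1_L5 > 0:
            raise InvalidInputError("skin distance must be positive")
        lv = tuple(self.sensor_levels)
        if not 4 <= len(lv) <= 17:
            raise InvalidInputError("need between 4 and 17 sensor levels")
        idx = [level_index(l) for l in lv]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise InvalidInputError("sensor levels must be distinct and ordered caudal->cranial")
        if "L5" not in lv or "T1" not in lv:
            raise InvalidInputError("sensor levels must include the chain endpoints L5 and T1")
        object.__setattr__(self, "sensor_levels", lv)


@dataclass(frozen=True)
class TPMResult:
    """Everything the pipeline produces for one static capture."""

    subject: SubjectParams
    sensor_eulers: Mapping[str, EulerZYX]          # after anteversion, before correction
    predicted_posture: SpinePosture
    offsets: Mapping[str, float]                   # rad, per instrumented level
    corrected_posture: SpinePosture                # corrected orientations, unscaled
    scale_factor: float
    scaled_model: SpineModel
    final_posture: SpinePosture                    # corrected + scaled
    estimated_sensor_positions: Mapping[str, np.ndarray]  # cm, per instrumented level
    sensor_position_convention: str = field(default="skin", compare=False)


def interpolate_vertebral_orientations(
    levels: Sequence[str], eulers: Sequence[EulerZYX]
) -> list[EulerZYX]:
    """All 17 vertebral Euler triplets from the instrumented subset.

    Yaw, pitch and roll are unwrapped along the chain and interpolated
    independently with the shape-preserving piecewise cubic over vertebra
    index (L5=1 ... T1=17).  Instrumented levels are reproduced exactly;
    both chain endpoints must carry sensors (no extrapolation).
    """
    if len(levels) != len(eulers):
        raise InvalidInputError("levels and eulers must have equal length")
    if "L5" not in levels or "T1" not in levels:
        raise InvalidInputError("interpolation requires sensors at both L5 and T1")
    idx = np.array([level_index(l) + 1 for l in levels], dtype=float)
    if np.any(np.diff(idx) <= 0):
        raise InvalidInputError("instrumented levels must be ordered caudal->cranial")
    channels = np.array([[e.yaw, e.pitch, e.roll] for e in eulers])
    query = np.arange(1, 18, dtype=float)
    interp = np.empty((17, 3))
    for c in range(3):
        interp[:, c] = pchip_eval(idx, np.unwrap(channels[:, c]), query)
    return [EulerZYX(*row) for row in interp]


def apply_pelvis_anteversion(
    base_euler: EulerZYX, sex: str, sign: float = 1.0
) -> EulerZYX:
    """Add the sex-specific pelvic-anteversion pitch to the L5 triplet.

    The anteversion of the pelvis inclines the attached L5 further in the
    sagittal plane than the skin over it suggests, so +10 deg (male) or
    +14 deg (female) is added to the measured pitch; yaw and roll are
    untouched.  ``sign=-1`` flips the convention.
    """
    try:
        add = math.radians(ANTEVERSION_DEG[sex])
    except KeyError:
        raise InvalidInputError(f"sex must be 'male' or 'female', got {sex!r}") from None
    return EulerZYX(base_euler.yaw, base_euler.pitch + sign * add, base_euler.roll)


def _segment_vector(posture: SpinePosture, level: str) -> np.ndarray:
    """Skin-surface segment attached to ``level``: towards the superior
    neighbour's skin point (for T1, from T2's skin point up to T1's)."""
    i = level_index(level)
    if level == "T1":
        v = posture.skin_points[i] - posture.skin_points[i - 1]
    else:
        v = posture.skin_points[i + 1] - posture.skin_points[i]
    return v


def estimate_angular_offsets(
    posture: SpinePosture, sensor_levels: Sequence[str]
) -> dict[str, float]:
    """Sagittal skin-to-vertebra angular offset per instrumented level, rad.

    The offset is the signed angle (about the sensor's local +y axis)
    between the sensor's longitudinal axis and the skin-surface segment
    attached to the vertebra, measured in the sensor's sagittal plane:
    positive when the predicted skin segment tilts anteriorly of the
    sensor axis.  With this sign, subtracting the offset from the sensor
    pitch recovers the vertebral pitch exactly whenever the skin-to-bone
    offset is uniform along the chain, and to first order otherwise.
    """
    offsets: dict[str, float] = {}
    for lvl in sensor_levels:
        v = _segment_vector(posture, lvl)
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise PipelineError(f"degenerate skin segment at {lvl}")
        v_local = posture.orientation(lvl).inverse().apply(v)
        sag = math.hypot(v_local[0], v_local[2])
        if sag < 1e-9 * norm:
            raise PipelineError(f"skin segment at {lvl} has no sagittal component")
        offsets[lvl] = math.atan2(v_local[0], v_local[2])
    return offsets


def correct_orientations(
    sensor_eulers: Mapping[str, EulerZYX], offsets: Mapping[str, float]
) -> dict[str, EulerZYX]:
    """Subtract each level's sagittal offset from its pitch.

    Implemented as a rotation about the intermediate y' axis of the
    Z-Y'-X'' decomposition, which leaves yaw and roll untouched and
    coincides with a rotation about the sensor's medial-lateral axis when
    roll is zero.
    """
    if set(sensor_eulers) != set(offsets):
        raise InvalidInputError(
            f"offset levels {sorted(offsets)} do not match sensor levels {sorted(sensor_eulers)}"
        )
    return {
        lvl: EulerZYX(e.yaw, e.pitch - offsets[lvl], e.roll)
        for lvl, e in sensor_eulers.items()
    }


def compute_scale_factor(measured: float, posture: SpinePosture) -> float:
    """Subject scale: measured skin distance / estimated skin arc length."""
    if not measured > 0:
        raise InvalidInputError("measured skin distance must be positive")
    arc = posture.skin_arc_length_T1_L5
    if not arc > 0:
        raise PipelineError("estimated skin arc length is non-positive")
    return measured / arc


def _pose_from_eulers(
    model: SpineModel, levels: Sequence[str], eulers: Sequence[EulerZYX]
) -> tuple[SpinePosture, list[EulerZYX]]:
    all_eulers = interpolate_vertebral_orientations(levels, eulers)
    quats = [quat_from_euler(e) for e in all_eulers]
    return forward_kinematics(model, quats), all_eulers


def run_tpm(
    readings: Sequence[SensorReading],
    cal: CalibrationSet | None,
    subject: SubjectParams,
    model: SpineModel,
    anteversion_sign: float = 1.0,
    sensor_position: str = "skin",
    correction_passes: int = 1,
    heading_t0: float | None = None,
) -> TPMResult:
    """Full posture estimation for one static standing capture.

    ``readings`` may span a capture window; they are plate-corrected (if
    ``cal`` is given), heading-normalised on the base sensor, and
    time-averaged per level before estimation.  ``sensor_position``
    chooses the reported estimated sensor point: ``"skin"`` (skin point,
    default — the sensor sits on the skin) or ``"spinous_tip"``.
    ``correction_passes`` > 1 re-estimates offsets on the corrected
    posture (off by default; a single predict->correct pass is standard).
    """
    if sensor_position not in ("skin", "spinous_tip"):
        raise InvalidInputError("sensor_position must be 'skin' or 'spinous_tip'")
    if correction_passes < 1:
        raise InvalidInputError("correction_passes must be >= 1")
    if cal is not None:
        readings = apply_corrections(readings, cal)
    readings = normalize_heading(readings, base_level="L5", t0=heading_t0)
    mean_orients = time_average_readings(readings)
    missing = [l for l in subject.sensor_levels if l not in mean_orients]
    if missing:
        raise PipelineError(f"no readings for instrumented levels {missing}")

    levels = list(subject.sensor_levels)
    sensor_eulers: dict[str, EulerZYX] = {
        lvl: euler_from_quat(mean_orients[lvl]) for lvl in levels
    }
    sensor_eulers["L5"] = apply_pelvis_anteversion(
        sensor_eulers["L5"], subject.sex, sign=anteversion_sign
    )

    # (1)-(2) predict
    predicted, _ = _pose_from_eulers(
        model, levels, [sensor_eulers[l] for l in levels]
    )
    # (3)-(4) estimate offsets on the predicted posture, subtract, re-pose.
    # The base (L5) is excluded: its skin-to-vertebra correction is the
    # anteversion constant already applied, and its skin segment is
    # dominated by the lower-lumbar soft-tissue step, which makes the
    # segment direction an unreliable offset reference there.
    offset_levels = [l for l in levels if l != "L5"]
    current = dict(sensor_eulers)
    posture = predicted
    offsets: dict[str, float] = {}
    for _ in range(correction_passes):
        step = estimate_angular_offsets(posture, offset_levels)
        offsets = {l: offsets.get(l, 0.0) + step[l] for l in offset_levels}
        corrected_subset = correct_orientations(
            {l: current[l] for l in offset_levels}, step
        )
        current.update(corrected_subset)
        posture, _ = _pose_from_eulers(model, levels, [current[l] for l in levels])
    corrected = posture
    for lvl in offset_levels:
        log.info("angular offset at %s: %+.2f deg", lvl, math.degrees(offsets[lvl]))

    # (5) scale so the estimated skin arc matches the tape measurement
    s = compute_scale_factor(subject.skin_distance_T1_L5, corrected)
    scaled = scale_model(model, s * model.scale)
    final, _ = _pose_from_eulers(scaled, levels, [current[l] for l in levels])
    log.info(
        "scale factor %.4f (measured %.1f cm / estimated %.1f cm)",
        s, subject.skin_distance_T1_L5, corrected.skin_arc_length_T1_L5,
    )

    # (6) estimated sensor positions at the instrumented levels
    points = final.skin_points if sensor_position == "skin" else final.spinous_tips
    est = {lvl: points[level_index(lvl)].copy() for lvl in levels}
    return TPMResult(
        subject=subject,
        sensor_eulers=sensor_eulers,
        predicted_posture=predicted,
        offsets=offsets,
        corrected_posture=corrected,
        scale_factor=s,
        scaled_model=scaled,
        final_posture=final,
        estimated_sensor_positions=est,
        sensor_position_convention=sensor_position,
    )
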