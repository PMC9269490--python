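"""Accuracy assessment: check-point position errors and configuration sweeps.

The estimate is validated against optically measured sensor positions:
both point sets are expressed with the base (L5) sensor at the origin —
orientation sensors carry no position, so only shape is comparable — and
the Euclidean distance at each remaining instrumented level is a
check-point error, reported in mm.  Under the full 6-sensor layout the
check-points are sensors #2..#6 at L1, T10, T7, T4 and T1 (e2..e6).

A configuration sweep reruns the estimation with 4-6 of the sensors and
reports the same five check-point errors for each layout; excluded
sensors contribute nothing to the estimate (their levels are filled by
interpolation) but still serve as check-points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .model import SpineModel, build_default_model, level_index
from .pipeline import SubjectParams, run_tpm
from .rotations import RotationQ, euler_from_quat
from .sensors import CalibrationSet, MarkerCluster, SensorReading, cluster_pose

__all__ = [
    "PAPER_CONFIGURATIONS",
    "CHECK_LEVELS",
    "ErrorReport",
    "SubjectRecord",
    "parse_configuration",
    "position_errors",
    "measured_positions_from_clusters",
    "configuration_sweep",
]

log = logging.getLogger(__name__)

#: The seven studied sensor layouts (4-6 sensors, endpoints always kept).
PAPER_CONFIGURATIONS: tuple[str, ...] = (
    "L5-L1-T10-T7-T4-T1",
    "L5-L1-T10-T7-T1",
    "L5-L1-T10-T4-T1",
    "L5-L1-T7-T4-T1",
    "L5-L1-T7-T1",
    "L5-L1-T10-T1",
    "L5-L1-T4-T1",
)

#: Check-point levels (sensors #2..#6 of the full layout; #1 = L5 base).
CHECK_LEVELS: tuple[str, ...] = ("L1", "T10", "T7", "T4", "T1")


@dataclass(frozen=True)
class ErrorReport:
    """Check-point errors for one subject (or aggregate) and configuration."""

    errors_mm: Mapping[str, float]
    mean_mm: float
    configuration: str = ""
    source: str = ""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's capture: sensor data plus optically measured positions."""

    subject: SubjectParams
    imu_readings: Sequence[SensorReading] = ()
    marker_clusters: Mapping[str, MarkerCluster] = field(default_factory=dict)
    cal: CalibrationSet | None = None
    label: str = ""


def parse_configuration(label: str) -> tuple[str, ...]:
    """Parse a layout label like ``"L5-L1-T10-T7-T1"`` into ordered levels."""
    parts = label.split("-")
    levels = []
    for p in parts:
        p = p.strip()
        if not p:
            raise InvalidInputError(f"empty level in configuration {label!r}")
        level_index(p)  # validates
        levels.append(p)
    return tuple(levels)


def position_errors(
    estimated: Mapping[str, Sequence[float]],
    measured: Mapping[str, Sequence[float]],
    base_level: str = "L5",
    units: str = "cm",
) -> ErrorReport:
    """Per-level Euclidean errors after translating both sets to the base.

    Inputs are per-level 3D points (default cm); errors are reported in mm
    over the levels shared by both sets, excluding the base.  Any common
    rigid translation of either set cancels by construction.
    """
    if base_level not in estimated or base_level not in measured:
        raise InvalidInputError(f"base level {base_level!r} missing from a point set")
    factor = {"cm": 10.0, "mm": 1.0}.get(units)
    if factor is None:
        raise InvalidInputError("units must be 'cm' or 'mm'")
    shared = [
        lvl for lvl in estimated if lvl in measured and lvl != base_level
    ]
    if not shared:
        raise InvalidInputError("no shared non-base levels to compare")
    e0 = np.asarray(estimated[base_level], dtype=float)
    m0 = np.asarray(measured[base_level], dtype=float)
    errors = {}
    for lvl in sorted(shared, key=level_index):
        d = (np.asarray(estimated[lvl], dtype=float) - e0) - (
            np.asarray(measured[lvl], dtype=float) - m0
        )
        errors[lvl] = float(np.linalg.norm(d)) * factor
    return ErrorReport(errors_mm=errors, mean_mm=float(np.mean(list(errors.values()))))


def measured_positions_from_clusters(
    clusters: Mapping[str, MarkerCluster], base_level: str = "L5"
) -> dict[str, np.ndarray]:
    """Optically measured sensor positions, cm, base at origin, heading cancelled.

    Marker coordinates are mm; each cluster's pose gives the sensor point.
    The whole optical point set is rotated about the base sensor by the
    negative initial yaw of the base cluster so the optical frame shares
    the heading-normalised frame of the estimates.
    """
    if base_level not in clusters:
        raise InvalidInputError(f"base level {base_level!r} missing from clusters")
    poses = {lvl: cluster_pose(c) for lvl, c in clusters.items()}
    psi = euler_from_quat(poses[base_level].rotation).yaw
    rz = RotationQ.about_z(-psi)
    p0 = poses[base_level].sensor_position
    return {
        lvl: rz.apply(pose.sensor_position - p0) / 10.0
        for lvl, pose in poses.items()
    }


def _estimated_positions(result, levels: Sequence[str]) -> dict[str, np.ndarray]:
    pts = (
        result.final_posture.skin_points
        if result.sensor_position_convention == "skin"
        else result.final_posture.spinous_tips
    )
    return {lvl: pts[level_index(lvl)] for lvl in levels}


def configuration_sweep(
    dataset: Sequence[SubjectRecord],
    configs: Sequence[str] = PAPER_CONFIGURATIONS,
    source: str = "imu",
    model: SpineModel | None = None,
    sensor_position: str = "skin",
) -> pd.DataFrame:
    """Mean check-point errors per sensor layout over a dataset.

    For each configuration, each subject's estimation is rerun using only
    that layout's sensors; estimated positions at all five check-point
    levels (instrumented or not) are compared with the optical
    measurements.  Returns a table with one row per configuration and
    columns n_sensors, e2..e6 (mm, labelled with their levels) and mean.
    """
    if source not in ("imu", "markers"):
        raise InvalidInputError("source must be 'imu' or 'markers'")
    base_model = model or build_default_model()
    rows = []
    for label in configs:
        try:
            levels = parse_configuration(label)
            if "L5" not in levels or "T1" not in levels:
                raise InvalidInputError("configuration must contain L5 and T1")
        except InvalidInputError as exc:
            log.warning("skipping configuration %r: %s", label, exc)
            continue
        per_level: dict[str, list[float]] = {lvl: [] for lvl in CHECK_LEVELS}
        for rec in dataset:
            measured = measured_positions_from_clusters(rec.marker_clusters)
            if source == "imu":
                readings = [r for r in rec.imu_readings if r.level in levels]
            else:
                readings = [
                    SensorReading(lvl, 0.0, cluster_pose(c).rotation)
                    for lvl, c in rec.marker_clusters.items()
                    if lvl in levels
                ]
            subject = SubjectParams(
                sex=rec.subject.sex,
                skin_distance_T1_L5=rec.subject.skin_distance_T1_L5,
                sensor_levels=levels,
            )
            result = run_tpm(
                readings, rec.cal, subject, base_model, sensor_position=sensor_position
            )
            est = _estimated_positions(result, ["L5", *CHECK_LEVELS])
            report = position_errors(est, measured)
            for lvl, e in report.errors_mm.items():
                if lvl in per_level:
                    per_level[lvl].append(e)
        row: dict[str, object] = {
            "configuration": label,
            "n_sensors": len(levels),
        }
        means = []
        for k, lvl in enumerate(CHECK_LEVELS, start=2):
            m = float(np.mean(per_level[lvl])) if per_level[lvl] else math.nan
            row[f"e{k}_{lvl}"] = m
            means.append(m)
        row["mean"] = float(np.nanmean(means))
        rows.append(row)
    return pd.DataFrame(rows).set_index("configuration")
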