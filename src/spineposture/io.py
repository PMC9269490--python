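"""Readers and writers for the on-disk formats.

Quaternions are serialized scalar-first (w, x, y, z).  Geometry is cm in
model/result files; marker trajectories are mm (the TRC convention);
angles in result files are degrees.  Readers reject malformed input with
errors naming file and line rather than silently coercing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .model import SpineModel
from .pipeline import SubjectParams, TPMResult
from .rotations import RotationQ
from .sensors import CalibrationSet, MarkerCluster, SensorReading, fuse_imu_stream

__all__ = [
    "read_imu_csv",
    "read_marker_trc",
    "read_subject_yaml",
    "write_subject_yaml",
    "read_model_yaml",
    "write_model_yaml",
    "read_calibration_json",
    "write_calibration_json",
    "write_result_json",
    "read_result_json",
]

RESULT_SCHEMA_VERSION = 1

_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_RAW_COLS = ["gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]


def read_imu_csv(path: str | Path, beta: float = 0.1) -> list[SensorReading]:
    """Read sensor orientations from CSV.

    Quaternion mode needs columns ``time_s, sensor_id, qw, qx, qy, qz``
    (quaternions within 1e-3 of unit norm are renormalized, larger
    deviations rejected).  Raw mode needs ``time_s, sensor_id, gx..gz
    (rad/s), ax..az (g), mx..mz (a.u.)`` and runs gradient-descent MARG
    fusion per sensor.  Timestamps must be non-decreasing per sensor.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    base_cols = {"time_s", "sensor_id"}
    if not base_cols.issubset(df.columns):
        raise ParseError(f"{path}: missing required columns {sorted(base_cols - set(df.columns))}")
    if set(_QUAT_COLS).issubset(df.columns):
        mode = "quat"
    elif set(_RAW_COLS).issubset(df.columns):
        mode = "raw"
    else:
        raise ParseError(
            f"{path}: need either quaternion columns {_QUAT_COLS} or raw columns {_RAW_COLS}"
        )
    readings: list[SensorReading] = []
    for sensor, group in df.groupby("sensor_id", sort=False):
        t = group["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            bad = int(group.index[np.argmin(np.diff(t) >= 0) + 1])
            raise ParseError(
                f"{path}: line {bad + 2}: non-monotone time_s for sensor {sensor!r}"
            )
        if mode == "quat":
            q = group[_QUAT_COLS].to_numpy(dtype=float)
            norms = np.linalg.norm(q, axis=1)
            bad = np.flatnonzero(np.abs(norms - 1.0) >= 1e-3)
            if bad.size:
                line = int(group.index[bad[0]]) + 2
                raise ParseError(
                    f"{path}: line {line}: quaternion norm {norms[bad[0]]:.6f} "
                    "deviates from 1 by more than 1e-3"
                )
            for ti, qi in zip(t, q):
                readings.append(SensorReading(str(sensor), float(ti), RotationQ(*qi)))
        else:
            gyro = group[["gx", "gy", "gz"]].to_numpy(dtype=float)
            accel = group[["ax", "ay", "az"]].to_numpy(dtype=float)
            mag = group[["mx", "my", "mz"]].to_numpy(dtype=float)
            quats = fuse_imu_stream(t, gyro, accel, mag, beta=beta)
            for ti, qi in zip(t, quats):
                readings.append(SensorReading(str(sensor), float(ti), qi))
    readings.sort(key=lambda r: r.time)
    return readings


@dataclass(frozen=True)
class TrcData:
    """Marker trajectories grouped per sensor: arrays of shape (n_frames, 3, 3) mm."""

    times: np.ndarray
    clusters: Mapping[str, np.ndarray]
    gap_frames: tuple[int, ...] = ()

    def frame_clusters(
        self,
        frame: int,
        template: np.ndarray,
        sensor_point_local: np.ndarray | None = None,
    ) -> dict[str, MarkerCluster]:
        point = np.zeros(3) if sensor_point_local is None else sensor_point_local
        return {
            sensor: MarkerCluster(
                markers=traj[frame],
                template=np.asarray(template, dtype=float),
                sensor_point_local=point,
                level=sensor,
            )
            for sensor, traj in self.clusters.items()
        }


def read_marker_trc(path: str | Path, units: str | None = None) -> TrcData:
    """Read a TRC marker file; markers named ``{sensor}_1..3`` are grouped.

    Coordinates are returned in mm.  Files in meters are converted only
    when ``units="m"`` is passed explicitly; frames with NaN coordinates
    are reported in ``gap_frames``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC file ({len(lines)} lines)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    file_units = header.get("Units", "mm").strip()
    if file_units == "mm":
        factor = 1.0
    elif file_units == "m":
        if units != "m":
            raise ParseError(
                f"{path}: line 3: Units is 'm'; pass units='m' to convert to mm"
            )
        factor = 1000.0
    else:
        raise ParseError(f"{path}: line 3: unsupported Units {file_units!r}")
    name_row = lines[3].split("\t")
    marker_names = [n.strip() for n in name_row[2:] if n.strip()]
    groups: dict[str, list[str]] = {}
    for name in marker_names:
        if "_" not in name:
            raise ParseError(f"{path}: line 4: marker {name!r} lacks a '{{sensor}}_{{k}}' name")
        sensor = name.rsplit("_", 1)[0]
        groups.setdefault(sensor, []).append(name)
    for sensor, names in groups.items():
        if len(names) != 3:
            raise ParseError(
                f"{path}: line 4: sensor {sensor!r} has {len(names)} markers, need 3"
            )
    times = []
    data_rows = []
    for ln, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            times.append(float(parts[1]))
            vals = [float(p) if p.strip() else math.nan for p in parts[2:]]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {ln}: bad data row: {exc}") from exc
        if len(vals) < 3 * len(marker_names):
            raise ParseError(
                f"{path}: line {ln}: expected {3 * len(marker_names)} coordinates, got {len(vals)}"
            )
        data_rows.append(vals[: 3 * len(marker_names)])
    if not data_rows:
        raise ParseError(f"{path}: no data frames")
    data = np.asarray(data_rows, dtype=float) * factor
    col_of = {name: i for i, name in enumerate(marker_names)}
    clusters = {}
    for sensor, names in groups.items():
        idx = [col_of[n] for n in sorted(names)]
        traj = np.stack([data[:, 3 * i : 3 * i + 3] for i in idx], axis=1)
        clusters[sensor] = traj
    gap = tuple(int(i) for i in np.flatnonzero(np.isnan(data).any(axis=1)))
    return TrcData(times=np.asarray(times), clusters=clusters, gap_frames=gap)


def write_marker_trc(
    clusters: Mapping[str, MarkerCluster],
    path: str | Path,
    sample_rate: float = 100.0,
) -> None:
    """Write one static frame of clusters as a minimal standard TRC (mm)."""
    path = Path(path)
    sensors = list(clusters)
    names = [f"{s}_{k}" for s in sensors for k in (1, 2, 3)]
    n_markers = len(names)
    head = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{sample_rate:g}\t{sample_rate:g}\t1\t{n_markers}\tmm\t{sample_rate:g}\t1\t1",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, n_markers + 1)),
        "",
    ]
    coords = []
    for s in sensors:
        m = clusters[s].markers
        order = sorted(range(3))  # markers stored in name order _1.._3
        for k in order:
            coords.extend(f"{v:.6f}" for v in m[k])
    head.append("1\t0.000000\t" + "\t".join(coords))
    path.write_text("\n".join(head) + "\n")


def read_subject_yaml(path: str | Path) -> SubjectParams:
    path = Path(path)
    try:
        d = yaml.safe_load(path.read_text())
        return SubjectParams(
            sex=d["sex"],
            skin_distance_T1_L5=float(d["skin_distance_cm"]),
            sensor_levels=tuple(d.get("sensor_levels", ("L5", "L1", "T10", "T7", "T4", "T1"))),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid subject file: {exc}") from exc


def write_subject_yaml(subject: SubjectParams, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "sex": subject.sex,
                "skin_distance_cm": float(subject.skin_distance_T1_L5),
                "sensor_levels": list(subject.sensor_levels),
            },
            sort_keys=False,
        )
    )


def read_model_yaml(path: str | Path) -> SpineModel:
    path = Path(path)
    try:
        return SpineModel.from_dict(yaml.safe_load(path.read_text()))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid model file: {exc}") from exc


def write_model_yaml(model: SpineModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def read_calibration_json(path: str | Path) -> CalibrationSet:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
        corrections = {
            sensor: RotationQ(*q) for sensor, q in d["corrections_wxyz"].items()
        }
        return CalibrationSet(corrections=corrections, reference=d["reference"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid calibration file: {exc}") from exc


def write_calibration_json(cal: CalibrationSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "reference": cal.reference,
                "corrections_wxyz": {
                    s: [q.w, q.x, q.y, q.z] for s, q in cal.corrections.items()
                },
                "plate_spread_deg": {
                    s: round(v, 4) for s, v in cal.spreads_deg.items()
                },
            },
            indent=2,
        )
    )


def _posture_records(posture) -> list[dict]:
    return [
        {
            "level": lvl,
            "quaternion_wxyz": [q.w, q.x, q.y, q.z],
            "joint_cm": posture.joints[i].tolist(),
            "spinous_tip_cm": posture.spinous_tips[i].tolist(),
            "skin_point_cm": posture.skin_points[i].tolist(),
        }
        for i, (lvl, q) in enumerate(zip(posture.levels, posture.orientations))
    ]


def write_result_json(result: TPMResult, path: str | Path) -> None:
    """Serialize a pipeline result; numbers keep full float precision
    (except offsets, stated in degrees with 6 decimals by contract)."""
    doc = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "subject": {
            "sex": result.subject.sex,
            "skin_distance_cm": result.subject.skin_distance_T1_L5,
            "sensor_levels": list(result.subject.sensor_levels),
        },
        "scale_factor": result.scale_factor,
        "offsets_deg": {
            lvl: round(math.degrees(v), 6) for lvl, v in result.offsets.items()
        },
        "sensor_position_convention": result.sensor_position_convention,
        "estimated_sensor_positions_cm": {
            lvl: p.tolist() for lvl, p in result.estimated_sensor_positions.items()
        },
        "skin_arc_length_T1_L5_cm": result.final_posture.skin_arc_length_T1_L5,
        "posture": _posture_records(result.final_posture),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_result_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if "schema_version" not in doc:
        raise ParseError(f"{path}: missing schema_version")
    return doc
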