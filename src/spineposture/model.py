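"""The 17-body thoracolumbar multibody model and its forward kinematics.

The spine is modelled as an open chain of 17 rigid segments (L5..L1,
T12..T1, caudal->cranial) linked by ideal spherical joints, with the base
(L5) origin fixed — orientation sensors provide no positions — giving
3 x 17 = 51 rotational degrees of freedom.

Each segment carries a local frame with +z longitudinal (toward the
superior vertebra), +x anterior and +y to the left.  The skin surface over
a vertebra lies posteriorly: spinous-process tip at -x by the spinous
length, skin point further out by the soft-tissue thickness (plus an extra
gluteal/adipose term at L5).  The 17 skin points are joined by a natural
cubic spline whose T1-L5 arc length is the quantity matched against the
tape-measured skin distance when scaling the model to a subject.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidInputError
from .rotations import RotationQ, Spline3D, fit_skin_spline, pchip_eval

__all__ = [
    "LEVELS",
    "LUMBAR_LEVELS",
    "THORACIC_LEVELS",
    "VertebraGeometry",
    "SpineModel",
    "SpinePosture",
    "build_default_model",
    "forward_kinematics",
    "scale_model",
]

#: Vertebral levels, caudal -> cranial (model order; L5 is the fixed base).
LEVELS: tuple[str, ...] = (
    "L5", "L4", "L3", "L2", "L1",
    "T12", "T11", "T10", "T9", "T8", "T7",
    "T6", "T5", "T4", "T3", "T2", "T1",
)
LUMBAR_LEVELS = LEVELS[:5]
THORACIC_LEVELS = LEVELS[5:]

_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}


def level_index(level: str) -> int:
    """0-based chain index of a vertebral level (L5 = 0 ... T1 = 16)."""
    try:
        return _LEVEL_INDEX[level]
    except KeyError:
        raise InvalidInputError(f"unknown vertebral level {level!r}") from None


@dataclass(frozen=True)
class VertebraGeometry:
    """Per-segment geometry, all lengths in cm (unscaled)."""

    level: str
    body_height: float
    spinous_length: float
    soft_tissue: float
    extra_tissue: float = 0.0

    def __post_init__(self) -> None:
        if self.level not in _LEVEL_INDEX:
            raise InvalidInputError(f"unknown vertebral level {self.level!r}")
        if min(self.body_height, self.spinous_length, self.soft_tissue) <= 0:
            raise InvalidInputError(f"{self.level}: lengths must be positive")
        if self.extra_tissue < 0:
            raise InvalidInputError(f"{self.level}: extra_tissue must be >= 0")

    @property
    def skin_offset(self) -> float:
        """Total posterior displacement joint->skin, cm (unscaled)."""
        return self.spinous_length + self.soft_tissue + self.extra_tissue


@dataclass(frozen=True)
class SpineModel:
    """Ordered 17-segment chain with a fixed base and a global scale."""

    segments: tuple[VertebraGeometry, ...]
    base_position: np.ndarray = field(
        default_factory=lambda: np.zeros(3), compare=False
    )
    scale: float = 1.0

    def __post_init__(self) -> None:
        if tuple(s.level for s in self.segments) != LEVELS:
            raise InvalidInputError(
                "model must have exactly the 17 levels L5..T1 in caudal->cranial order"
            )
        if self.scale <= 0:
            raise InvalidInputError("scale must be positive")
        object.__setattr__(
            self, "base_position", np.asarray(self.base_position, dtype=float)
        )

    @property
    def levels(self) -> tuple[str, ...]:
        return LEVELS

    def segment(self, level: str) -> VertebraGeometry:
        return self.segments[level_index(level)]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def dof(self) -> int:
        """Rotational DOFs: 3 per spherical joint, base position fixed."""
        return 3 * self.n_segments

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "base_position_cm": self.base_position.tolist(),
            "segments": [
                {
                    "level": s.level,
                    "body_height_cm": s.body_height,
                    "spinous_length_cm": s.spinous_length,
                    "soft_tissue_cm": s.soft_tissue,
                    "extra_tissue_cm": s.extra_tissue,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpineModel":
        segs = tuple(
            VertebraGeometry(
                level=s["level"],
                body_height=s["body_height_cm"],
                spinous_length=s["spinous_length_cm"],
                soft_tissue=s["soft_tissue_cm"],
                extra_tissue=s.get("extra_tissue_cm", 0.0),
            )
            for s in d["segments"]
        )
        return cls(
            segments=segs,
            base_position=np.asarray(d.get("base_position_cm", (0.0, 0.0, 0.0))),
            scale=float(d.get("scale", 1.0)),
        )


@dataclass(frozen=True)
class SpinePosture:
    """A posed model: per-level orientation and derived global geometry (cm)."""

    levels: tuple[str, ...]
    orientations: tuple[RotationQ, ...]
    joints: np.ndarray          # (17, 3) joint centres
    spinous_tips: np.ndarray    # (17, 3)
    skin_points: np.ndarray     # (17, 3)
    skin_spline: Spline3D
    skin_arc_length_T1_L5: float

    def index(self, level: str) -> int:
        return level_index(level)

    def orientation(self, level: str) -> RotationQ:
        return self.orientations[self.index(level)]

    def joint(self, level: str) -> np.ndarray:
        return self.joints[self.index(level)]

    def spinous_tip(self, level: str) -> np.ndarray:
        return self.spinous_tips[self.index(level)]

    def skin_point(self, level: str) -> np.ndarray:
        return self.skin_points[self.index(level)]


def _load_default_geometry() -> dict:
    ref = importlib.resources.files("spineposture").joinpath(
        "data/vertebral_geometry.yaml"
    )
    return yaml.safe_load(ref.read_text())


def build_default_model(
    body_heights: Mapping[str, float] | None = None,
    base_position: Sequence[float] = (0.0, 0.0, 0.0),
) -> SpineModel:
    """Default 17-segment model.

    Spinous-process lengths are anchored at T1 (3.1 cm), T10 (4.6 cm),
    L1 (5.1 cm) and L5 (4.5 cm) and filled in between by monotone
    piecewise-cubic interpolation over vertebra index; soft tissue is
    1.35 cm at every level with an additional 1.7 cm at L5.  Body heights
    default to an average-adult table and may be overridden per subject.
    """
    geo = _load_default_geometry()
    heights = dict(geo["body_height_cm"])
    if body_heights is not None:
        heights.update(body_heights)
    anchors = geo["spinous_length_anchor_cm"]
    anchor_idx = sorted(level_index(lvl) + 1 for lvl in anchors)
    anchor_val = [anchors[LEVELS[i - 1]] for i in anchor_idx]
    spinous = pchip_eval(anchor_idx, anchor_val, np.arange(1, 18))
    soft = float(geo["soft_tissue_cm"])
    extra = dict(geo.get("extra_tissue_cm", {}))
    segments = tuple(
        VertebraGeometry(
            level=lvl,
            body_height=float(heights[lvl]),
            spinous_length=float(spinous[i]),
            soft_tissue=soft,
            extra_tissue=float(extra.get(lvl, 0.0)),
        )
        for i, lvl in enumerate(LEVELS)
    )
    return SpineModel(segments=segments, base_position=np.asarray(base_position))


def forward_kinematics(
    model: SpineModel, orientations: Sequence[RotationQ]
) -> SpinePosture:
    """Pose the chain from 17 global segment orientations (L5 -> T1).

    joint(L5) sits at the model base; each next joint stacks the scaled
    body height along the segment's local +z; spinous tip and skin point
    are displaced along local -x (posterior).  The skin spline is fitted
    through the 17 skin points and its full arc length reported.
    """
    if len(orientations) != model.n_segments:
        raise InvalidInputError(
            f"expected {model.n_segments} orientations, got {len(orientations)}"
        )
    s = model.scale
    n = model.n_segments
    joints = np.empty((n, 3))
    tips = np.empty((n, 3))
    skin = np.empty((n, 3))
    pos = model.base_position.astype(float).copy()
    for i, (seg, q) in enumerate(zip(model.segments, orientations)):
        joints[i] = pos
        tips[i] = pos + q.apply((-seg.spinous_length * s, 0.0, 0.0))
        skin[i] = pos + q.apply((-seg.skin_offset * s, 0.0, 0.0))
        pos = pos + q.apply((0.0, 0.0, seg.body_height * s))
    spline = fit_skin_spline(skin)
    return SpinePosture(
        levels=model.levels,
        orientations=tuple(orientations),
        joints=joints,
        spinous_tips=tips,
        skin_points=skin,
        skin_spline=spline,
        skin_arc_length_T1_L5=spline.arc_length(),
    )


def scale_model(model: SpineModel, s: float) -> SpineModel:
    """Model with scale set to ``s``; all posed geometry scales about the base."""
    if not np.isfinite(s) or s <= 0:
        raise InvalidInputError("scale factor must be positive and finite")
    return replace(model, scale=float(s))
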