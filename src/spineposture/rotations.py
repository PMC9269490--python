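"""Rotation algebra and interpolation primitives.

Conventions used throughout the package: the global frame has x pointing
anteriorly (the posterior->anterior axis), y medial-laterally (to the
subject's left) and z vertically up.  Euler angles are intrinsic Z-Y'-X''
— yaw about the vertical z, pitch about the intermediate y, roll about the
final x — the usual yaw-pitch-roll sequence for sensors whose heading is
defined about the shared vertical axis.

Quaternions are Hamilton, scalar-first (w, x, y, z), and represent
body->global rotations.  The double cover is resolved by canonicalising
w >= 0 on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError

__all__ = [
    "RotationQ",
    "EulerZYX",
    "Spline3D",
    "quat_from_euler",
    "euler_from_quat",
    "unwrap_angles",
    "pchip_eval",
    "fit_skin_spline",
    "arc_length",
]

_GIMBAL_EPS = 1e-6


@dataclass(frozen=True)
class RotationQ:
    """Unit quaternion (w, x, y, z), body->global, canonicalised to w >= 0."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        n = math.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if not math.isfinite(n) or n < 1e-12:
            raise InvalidInputError("quaternion norm is zero or non-finite")
        s = 1.0 / n
        if self.w < 0.0:
            s = -s
        object.__setattr__(self, "w", self.w * s)
        object.__setattr__(self, "x", self.x * s)
        object.__setattr__(self, "y", self.y * s)
        object.__setattr__(self, "z", self.z * s)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RotationQ":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_scipy(cls, r: Rotation) -> "RotationQ":
        x, y, z, w = r.as_quat()
        return cls(w, x, y, z)

    @classmethod
    def from_axis_angle(cls, axis: Sequence[float], angle: float) -> "RotationQ":
        a = np.asarray(axis, dtype=float)
        return cls.from_scipy(Rotation.from_rotvec(a / np.linalg.norm(a) * angle))

    @classmethod
    def about_z(cls, angle: float) -> "RotationQ":
        return cls(math.cos(angle / 2), 0.0, 0.0, math.sin(angle / 2))

    @classmethod
    def about_y(cls, angle: float) -> "RotationQ":
        return cls(math.cos(angle / 2), 0.0, math.sin(angle / 2), 0.0)

    @classmethod
    def about_x(cls, angle: float) -> "RotationQ":
        return cls(math.cos(angle / 2), math.sin(angle / 2), 0.0, 0.0)

    # -- algebra ----------------------------------------------------------
    def as_scipy(self) -> Rotation:
        return Rotation.from_quat([self.x, self.y, self.z, self.w])

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def as_matrix(self) -> np.ndarray:
        return self.as_scipy().as_matrix()

    def compose(self, other: "RotationQ") -> "RotationQ":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RotationQ.from_scipy(self.as_scipy() * other.as_scipy())

    def __mul__(self, other: "RotationQ") -> "RotationQ":
        return self.compose(other)

    def inverse(self) -> "RotationQ":
        return RotationQ(self.w, -self.x, -self.y, -self.z)

    def apply(self, vec: Sequence[float]) -> np.ndarray:
        return self.as_scipy().apply(np.asarray(vec, dtype=float))

    def angle_to(self, other: "RotationQ") -> float:
        """Magnitude of the relative rotation, in radians."""
        return float((self.as_scipy().inv() * other.as_scipy()).magnitude())


@dataclass(frozen=True)
class EulerZYX:
    """Intrinsic yaw-pitch-roll triplet in radians.

    ``gimbal_lock`` marks triplets extracted at |pitch| = pi/2, where yaw
    is set to zero by convention and roll absorbs the free angle.
    """

    yaw: float
    pitch: float
    roll: float
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll])


def quat_from_euler(e: EulerZYX) -> RotationQ:
    """Quaternion of the intrinsic Z-Y'-X'' rotation Rz(yaw)·Ry(pitch)·Rx(roll)."""
    if not all(map(math.isfinite, (e.yaw, e.pitch, e.roll))):
        raise InvalidInputError("Euler angles must be finite")
    return RotationQ.from_scipy(
        Rotation.from_euler("ZYX", [e.yaw, e.pitch, e.roll])
    )


def euler_from_quat(q: RotationQ) -> EulerZYX:
    """Extract intrinsic Z-Y'-X'' angles; pitch in [-pi/2, pi/2].

    At gimbal lock (|pitch| within ~1e-6 of pi/2) the decomposition is
    degenerate: yaw is set to 0, roll absorbs the remaining angle and the
    result is flagged.
    """
    m = q.as_matrix()
    sp = float(np.clip(-m[2, 0], -1.0, 1.0))
    pitch = math.asin(sp)
    if math.pi / 2 - abs(pitch) < _GIMBAL_EPS:
        # R = Ry(±pi/2)·Rx(roll) once yaw is pinned to 0
        if pitch > 0:
            roll = math.atan2(m[0, 1], m[1, 1])
        else:
            roll = math.atan2(-m[0, 1], m[1, 1])
        return EulerZYX(0.0, pitch, roll, gimbal_lock=True)
    yaw = math.atan2(m[1, 0], m[0, 0])
    roll = math.atan2(m[2, 1], m[2, 2])
    return EulerZYX(yaw, pitch, roll)


def unwrap_angles(series: Iterable[float]) -> np.ndarray:
    """Remove ±2π jumps so successive differences lie in (-π, π]."""
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot unwrap an empty angle series")
    return np.unwrap(arr)


# Shape-preserving piecewise-cubic interpolation (Fritsch–Carlson/Butland
# slopes, the scheme behind Matlab's pchip); scipy provides the evaluator.
def pchip_eval(
    knots_x: Sequence[float], knots_y: Sequence[float], query_x: Sequence[float]
) -> np.ndarray:
    x = np.asarray(knots_x, dtype=float)
    y = np.asarray(knots_y, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("pchip requires at least 2 knots")
    if y.shape != x.shape:
        raise InvalidInputError("knots_x and knots_y must have equal length")
    if np.any(np.diff(x) <= 0):
        raise InvalidInputError("knot abscissae must be strictly increasing")
    return PchipInterpolator(x, y)(np.asarray(query_x, dtype=float))


class Spline3D:
    """Natural cubic spline through ordered 3D points, chord-length knots.

    Interpolates every knot exactly and is C² in the interior.  Arc length
    is computed per spline segment with fixed-order Gauss–Legendre
    quadrature, which is far below 1e-4 relative error for the smooth
    curves handled here.
    """

    _GL_ORDER = 16

    def __init__(self, t: np.ndarray, points: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.points = np.asarray(points, dtype=float)
        self._spline = CubicSpline(self.t, self.points, axis=0, bc_type="natural")
        self._deriv = self._spline.derivative()
        self._gl_nodes, self._gl_weights = np.polynomial.legendre.leggauss(
            self._GL_ORDER
        )

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def position(self, u) -> np.ndarray:
        return self._spline(u)

    def derivative(self, u) -> np.ndarray:
        return self._deriv(u)

    def arc_length(self, a: float | None = None, b: float | None = None) -> float:
        lo, hi = self.domain
        a = lo if a is None else float(a)
        b = hi if b is None else float(b)
        tol = 1e-9 * max(1.0, hi - lo)
        if a > b:
            raise InvalidInputError("arc_length requires a <= b")
        if a < lo - tol or b > hi + tol:
            raise InvalidInputError(
                f"parameters [{a}, {b}] outside spline domain [{lo}, {hi}]"
            )
        a, b = max(a, lo), min(b, hi)
        if b - a <= 0.0:
            return 0.0
        # split at interior knots so each panel integrates a single cubic
        cuts = self.t[(self.t > a) & (self.t < b)]
        edges = np.concatenate(([a], cuts, [b]))
        total = 0.0
        for u0, u1 in zip(edges[:-1], edges[1:]):
            half = 0.5 * (u1 - u0)
            mid = 0.5 * (u1 + u0)
            u = mid + half * self._gl_nodes
            speed = np.linalg.norm(self._deriv(u), axis=1)
            total += half * float(np.dot(self._gl_weights, speed))
        return total


def fit_skin_spline(points: Sequence[Sequence[float]]) -> Spline3D:
    """Natural cubic spline through ordered (caudal->cranial) 3D points.

    Parameterised by cumulative chord length, so the knot parameter is an
    approximate arc-length coordinate in the same units as the points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise InvalidInputError("need at least 3 ordered 3D points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise InvalidInputError("duplicate consecutive points in skin-point set")
    t = np.concatenate(([0.0], np.cumsum(seg)))
    return Spline3D(t, pts)


def arc_length(s: Spline3D, a: float | None = None, b: float | None = None) -> float:
    """Arc length of ``s`` between parameters ``a`` and ``b`` (defaults: full)."""
    return s.arc_length(a, b)
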