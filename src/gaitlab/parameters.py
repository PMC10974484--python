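"""Gait and balance parameter time series from 3D skeleton sequences.

Nine clinically motivated measurements are derived from the metric joint
positions, each one a building block for scoring items of standard
fall-risk tests:

* **speed** — displacement of the hip midpoint over 1-s sliding windows.
* **trajectory** — hip midpoint projected onto the ground plane
  (lateral = camera x, depth = camera z).
* **trunk swing** — inclination of the shoulder-to-shoulder line with
  respect to the camera horizontal plane; 0 deg = level shoulders.
* **separation of the arms** — elbow-shoulder-hip angle, per side.
* **arm support** — shoulder-elbow-wrist angle, per side; an extended arm
  reads ~180 deg, a push-off on a chair armrest bends it below ~100 deg.
* **separation of the heels** — lateral (x) distance between the ankles.
* **stride** — depth (z) difference between the ankles; its local maxima,
  reached when both feet are flat on the ground, approximate step length.
* **hand separation** — 3D distance between the wrists.
* **trunk tilt** — shoulder-hip-knee angle per side, plus the left/right
  mean; ~180 deg standing, ~120 deg seated.

All angles come from the three-joint formula
``alpha = arccos(AB.AC / (|AB| |AC|))`` with vertex A; values are in
degrees in [0, 180].  MISSING joints propagate to MISSING (NaN) samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .camera import MISSING
from .errors import DegenerateGeometryError
from . import skeleton as sk

_EPS = 1e-6  # minimum vector norm (meters) for a well-defined angle

VALID_SERIES_NAMES = frozenset({
    "speed", "trajectory", "trunk_swing",
    "arm_separation_left", "arm_separation_right",
    "arm_support_left", "arm_support_right",
    "heel_separation", "stride", "hand_separation",
    "trunk_tilt_left", "trunk_tilt_right", "trunk_tilt_mean",
})

_ANGLE_SERIES = frozenset(n for n in VALID_SERIES_NAMES
                          if "swing" in n or "tilt" in n or "arm" in n)


@dataclass
class ParameterSeries:
    """A named, unit-carrying time series; MISSING samples are NaN."""

    name: str
    units: str
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.units not in ("m/s", "m", "degrees"):
            raise ValueError(f"unknown units {self.units!r}")
        finite = self.v[np.isfinite(self.v)]
        if self.units == "degrees" and finite.size and (
                finite.min() < -1e-9 or finite.max() > 180 + 1e-9):
            raise ValueError("angle values must lie in [0, 180] degrees")
        if self.units in ("m", "m/s") and finite.size and finite.min() < -1e-9:
            raise ValueError("distances and speeds must be non-negative")

    # -- serialization (exact float round trip via JSON repr) ----------
    def to_dict(self) -> dict:
        return {"name": self.name, "units": self.units,
                "t": self.t.tolist(),
                "v": [None if not np.isfinite(x) else x
                      for x in self.v.tolist()]}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSeries":
        v = [MISSING if x is None else x for x in d["v"]]
        return cls(d["name"], d["units"], np.array(d["t"]), np.array(v))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "ParameterSeries":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary(self) -> dict:
        """min / max / mean / final over the non-MISSING samples."""
        finite = self.v[np.isfinite(self.v)]
        if finite.size == 0:
            return {"min": None, "max": None, "mean": None, "final": None}
        return {"min": float(finite.min()), "max": float(finite.max()),
                "mean": float(finite.mean()), "final": float(finite[-1])}


@dataclass
class TrajectorySeries:
    """Ground-plane path of the hip midpoint: (lateral = x, depth = z)."""

    t: np.ndarray
    lateral: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        finite = np.isfinite(self.depth)
        if np.any(self.depth[finite] <= 0):
            raise ValueError("trajectory depth must be positive")

    def to_dict(self) -> dict:
        none = lambda a: [None if not np.isfinite(x) else x for x in a.tolist()]
        return {"name": "trajectory", "t": self.t.tolist(),
                "lateral": none(self.lateral), "depth": none(self.depth)}


# ----------------------------------------------------------------------
# Angle primitive

def joint_angle(a, b, c) -> float:
    """Angle (degrees) at vertex A between rays A->B and A->C.

    ``arccos`` of the normalized dot product, with the cosine clamped to
    [-1, 1] to absorb floating-point drift; result in [0, 180].
    """
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    ac = np.asarray(c, dtype=float) - a
    nab, nac = np.linalg.norm(ab), np.linalg.norm(ac)
    if nab < _EPS or nac < _EPS:
        raise DegenerateGeometryError(
            "zero-length vector: coincident joints")
    cosang = np.clip(np.dot(ab, ac) / (nab * nac), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _angle_series_values(J: np.ndarray, a: int, b: int, c: int) -> np.ndarray:
    """Vectorized per-frame vertex angle over a stacked (T, 33, 3) array."""
    ab = J[:, b] - J[:, a]
    ac = J[:, c] - J[:, a]
    nab = np.linalg.norm(ab, axis=1)
    nac = np.linalg.norm(ac, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cos = np.einsum("ij,ij->i", ab, ac) / (nab * nac)
        out = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        out[(nab < _EPS) | (nac < _EPS)] = MISSING
    return out


def _hip_mid(J: np.ndarray) -> np.ndarray:
    """(T, 3) hip midpoint; NaN rows where either hip is MISSING."""
    return 0.5 * (J[:, sk.LEFT_HIP] + J[:, sk.RIGHT_HIP])


# ----------------------------------------------------------------------
# The nine parameters

def speed_series(seq, window: float = 1.0,
                 ground_plane: bool = False) -> ParameterSeries:
    """Hip-midpoint displacement speed over sliding windows of ``window`` s.

    For every frame at time t >= t0 + window the value is
    ``|m(t) - m(t - window)| / window`` where m is the hip midpoint and the
    window start is the frame nearest t - window (it must fall within half
    a frame period, else the sample is MISSING).  ``ground_plane=True``
    drops the vertical (y) component before taking the norm; for level
    gait the difference is negligible.
    """
    t, J = sk.stack_sequence(seq)
    if t.size == 0 or t[-1] - t[0] < window:
        warnings.warn("sequence shorter than the speed window; empty series")
        return ParameterSeries("speed", "m/s", np.empty(0), np.empty(0))
    m = _hip_mid(J)
    if ground_plane:
        m = m[:, [0, 2]]
    half_dt = 0.5 * float(np.median(np.diff(t))) if t.size > 1 else 0.0
    keep = t >= t[0] + window
    idx = np.searchsorted(t, t[keep] - window)
    idx = np.clip(idx, 0, t.size - 1)
    prev = np.clip(idx - 1, 0, t.size - 1)
    idx = np.where(np.abs(t[prev] - (t[keep] - window))
                   < np.abs(t[idx] - (t[keep] - window)), prev, idx)
    ok = np.abs(t[idx] - (t[keep] - window)) <= half_dt + 1e-9
    disp = np.linalg.norm(m[keep] - m[idx], axis=1)
    v = np.where(ok, disp / window, MISSING)
    return ParameterSeries("speed", "m/s", t[keep], v)


def trajectory_series(seq) -> TrajectorySeries:
    """Hip midpoint projected onto the ground plane, per frame."""
    t, J = sk.stack_sequence(seq)
    m = _hip_mid(J)
    return TrajectorySeries(t, m[:, 0], m[:, 2])


def trunk_swing(seq) -> ParameterSeries:
    """Shoulder-line inclination w.r.t. the camera horizontal plane.

    With shoulder vector s = left - right, the value is
    ``atan(|s_y| / sqrt(s_x^2 + s_z^2))`` in degrees.  0 deg means level
    shoulders; the camera is assumed level.
    """
    t, J = sk.stack_sequence(seq)
    s = J[:, sk.LEFT_SHOULDER] - J[:, sk.RIGHT_SHOULDER]
    horiz = np.hypot(s[:, 0], s[:, 2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.degrees(np.arctan2(np.abs(s[:, 1]), horiz))
        v[np.linalg.norm(s, axis=1) < _EPS] = MISSING
    return ParameterSeries("trunk_swing", "degrees", t, v)


def _side(side: str, left, right):
    if side == "left":
        return left
    if side == "right":
        return right
    raise ValueError("side must be 'left' or 'right'")


def arm_separation(seq, side: str) -> ParameterSeries:
    """Elbow-shoulder-hip angle (vertex at the shoulder), one side."""
    t, J = sk.stack_sequence(seq)
    a = _side(side, sk.LEFT_SHOULDER, sk.RIGHT_SHOULDER)
    b = _side(side, sk.LEFT_ELBOW, sk.RIGHT_ELBOW)
    c = _side(side, sk.LEFT_HIP, sk.RIGHT_HIP)
    return ParameterSeries(f"arm_separation_{side}", "degrees", t,
                           _angle_series_values(J, a, b, c))


def arm_support_angle(seq, side: str) -> ParameterSeries:
    """Shoulder-elbow-wrist angle (vertex at the elbow), one side."""
    t, J = sk.stack_sequence(seq)
    a = _side(side, sk.LEFT_ELBOW, sk.RIGHT_ELBOW)
    b = _side(side, sk.LEFT_SHOULDER, sk.RIGHT_SHOULDER)
    c = _side(side, sk.LEFT_WRIST, sk.RIGHT_WRIST)
    return ParameterSeries(f"arm_support_{side}", "degrees", t,
                           _angle_series_values(J, a, b, c))


def heel_separation(seq, ground_plane: bool = False) -> ParameterSeries:
    """Lateral distance between the ankles.

    Frontal captures measure |x_left - x_right|; ``ground_plane=True``
    switches to the full x-z distance for oblique captures.
    """
    t, J = sk.stack_sequence(seq)
    d = J[:, sk.LEFT_ANKLE] - J[:, sk.RIGHT_ANKLE]
    v = np.hypot(d[:, 0], d[:, 2]) if ground_plane else np.abs(d[:, 0])
    return ParameterSeries("heel_separation", "m", t, v)


def stride_signal(seq) -> ParameterSeries:
    """Depth difference between the ankles, |z_left - z_right|, per frame."""
    t, J = sk.stack_sequence(seq)
    v = np.abs(J[:, sk.LEFT_ANKLE, 2] - J[:, sk.RIGHT_ANKLE, 2])
    return ParameterSeries("stride", "m", t, v)


def hand_separation(seq) -> ParameterSeries:
    """3D Euclidean distance between the wrists, per frame."""
    t, J = sk.stack_sequence(seq)
    v = np.linalg.norm(J[:, sk.LEFT_WRIST] - J[:, sk.RIGHT_WRIST], axis=1)
    return ParameterSeries("hand_separation", "m", t, v)


def trunk_tilt(seq, side: str) -> ParameterSeries:
    """Shoulder-hip-knee angle (vertex at the hip), one side."""
    t, J = sk.stack_sequence(seq)
    a = _side(side, sk.LEFT_HIP, sk.RIGHT_HIP)
    b = _side(side, sk.LEFT_SHOULDER, sk.RIGHT_SHOULDER)
    c = _side(side, sk.LEFT_KNEE, sk.RIGHT_KNEE)
    return ParameterSeries(f"trunk_tilt_{side}", "degrees", t,
                           _angle_series_values(J, a, b, c))


def trunk_tilt_mean(seq) -> ParameterSeries:
    """Mean of the left and right trunk tilt; MISSING if either side is."""
    left = trunk_tilt(seq, "left")
    right = trunk_tilt(seq, "right")
    return ParameterSeries("trunk_tilt_mean", "degrees", left.t,
                           0.5 * (left.v + right.v))


# ----------------------------------------------------------------------
# Event detectors

def detect_stride_lengths(sig: ParameterSeries, prominence: float = 0.05,
                          min_separation: float = 0.3,
                          smooth_window: int = 5) -> list[tuple[float, float]]:
    """Step lengths as local maxima of the (smoothed) stride signal.

    Peaks of the ankle depth-difference occur when both feet are flat on
    the ground, so their heights approximate step length.  Peaks need a
    prominence of at least ``prominence`` meters and ``min_separation``
    seconds between them.  Returns ``(timestamp, stride length)`` pairs.
    """
    if sig.t.size < 3:
        return []
    v = sk._running_median(sig.v, smooth_window) if smooth_window > 1 \
        else sig.v.copy()
    v = np.where(np.isfinite(v), v, 0.0)
    dt = float(np.median(np.diff(sig.t)))
    if dt <= 0 or 1.0 / dt < 10.0:
        raise ValueError("stride detection needs a >= 10 Hz signal")
    distance = max(1, int(np.ceil(min_separation / dt)))
    peaks, _ = find_peaks(v, prominence=prominence, distance=distance)
    return [(float(sig.t[p]), float(v[p])) for p in peaks]


@dataclass
class ArmSupportResult:
    """Outcome of the sit<->stand arm-support analysis."""

    used: bool
    windows: list = field(default_factory=list)  # (t_start, t_end) pairs
    min_angle: float | None = None  # minimum arm angle inside the windows


def detect_arm_support(trunk_mean: ParameterSeries,
                       arm_left: ParameterSeries,
                       arm_right: ParameterSeries,
                       stand_threshold: float = 140.0,
                       bend_threshold: float = 100.0,
                       pad: float = 1.0) -> ArmSupportResult:
    """Decide whether the arms were used to stand up or sit down.

    Sit<->stand transitions are located where the mean trunk tilt crosses
    ``stand_threshold`` (midway between the ~120 deg seated and >160 deg
    standing regimes).  Arm support is flagged when either arm's
    shoulder-elbow-wrist angle dips below ``bend_threshold`` within
    ``pad`` seconds of a transition; arm bends far from any transition
    (e.g. while comfortably seated) are ignored.
    """
    t, v = trunk_mean.t, trunk_mean.v
    finite = np.isfinite(v)
    tf, vf = t[finite], v[finite]
    if tf.size < 2:
        return ArmSupportResult(False)
    above = vf > stand_threshold
    cross = np.flatnonzero(above[1:] != above[:-1])
    if cross.size == 0:
        return ArmSupportResult(False)
    windows = []
    for c in cross:
        t0, t1 = tf[c] - pad, tf[c + 1] + pad
        if windows and t0 <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], t1))
        else:
            windows.append((t0, t1))
    min_angle = np.inf
    for arm in (arm_left, arm_right):
        for t0, t1 in windows:
            inside = (arm.t >= t0) & (arm.t <= t1) & np.isfinite(arm.v)
            if inside.any():
                min_angle = min(min_angle, float(arm.v[inside].min()))
    if not np.isfinite(min_angle):
        return ArmSupportResult(False, windows)
    return ArmSupportResult(min_angle < bend_threshold, windows, min_angle)
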