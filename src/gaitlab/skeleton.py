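"""33-landmark body topology and per-frame metric skeleton assembly.

The pose estimator emits, per video frame, 33 body landmarks in normalized
image coordinates (u = column / width, v = row / height, both in [0, 1])
plus a visibility score in [0, 1].  Joint indices follow the MediaPipe Pose
convention (0 nose, 11/12 shoulders, 13/14 elbows, 15/16 wrists, 23/24
hips, 25/26 knees, 27/28 ankles, ...).

`build_skeleton` combines a landmark frame with the registered depth
raster: each sufficiently-visible landmark is denormalized to a pixel, its
depth looked up (with dropout fill), and the pixel back-projected into a
metric 3D joint in the camera frame.  Joints below the visibility threshold
or over depth holes are MISSING (NaN rows).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from .camera import (CameraIntrinsics, DepthFrame, MISSING, backproject_pixel,
                     lookup_depth, round_half_up)
from .errors import LandmarkValidationError

log = logging.getLogger(__name__)

N_LANDMARKS = 33

LANDMARK_NAMES = [
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
]

# Joint index constants used by the parameter computations.
NOSE = 0
LEFT_SHOULDER, RIGHT_SHOULDER = 11, 12
LEFT_ELBOW, RIGHT_ELBOW = 13, 14
LEFT_WRIST, RIGHT_WRIST = 15, 16
LEFT_HIP, RIGHT_HIP = 23, 24
LEFT_KNEE, RIGHT_KNEE = 25, 26
LEFT_ANKLE, RIGHT_ANKLE = 27, 28
LEFT_HEEL, RIGHT_HEEL = 29, 30
LEFT_FOOT_INDEX, RIGHT_FOOT_INDEX = 31, 32

#: index permutation that swaps every left/right landmark pair.
MIRROR_INDEX = np.arange(N_LANDMARKS)
for _l, _r in [(1, 4), (2, 5), (3, 6), (7, 8), (9, 10), (11, 12), (13, 14),
               (15, 16), (17, 18), (19, 20), (21, 22), (23, 24), (25, 26),
               (27, 28), (29, 30), (31, 32)]:
    MIRROR_INDEX[_l], MIRROR_INDEX[_r] = _r, _l


@dataclass
class LandmarkFrame:
    """One timestamped frame of 33 normalized landmarks.

    ``landmarks`` is a (33, 3) array of ``(u, v, visibility)`` rows, all in
    [0, 1].
    """

    timestamp: float
    landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (N_LANDMARKS, 3):
            raise LandmarkValidationError(
                f"expected ({N_LANDMARKS}, 3) landmarks, got "
                f"{self.landmarks.shape}")
        if np.any(self.landmarks < 0) or np.any(self.landmarks > 1):
            raise LandmarkValidationError(
                "landmark u, v and visibility must lie in [0, 1]")


@dataclass
class Skeleton3D:
    """33 metric 3D joints in the camera frame; MISSING joints are NaN rows.

    Every non-MISSING joint has z > 0 (in front of the camera).
    """

    timestamp: float
    joints: np.ndarray

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (N_LANDMARKS, 3):
            raise LandmarkValidationError(
                f"expected ({N_LANDMARKS}, 3) joints, got "
                f"{self.joints.shape}")
        finite = np.all(np.isfinite(self.joints), axis=1)
        if np.any(self.joints[finite, 2] <= 0):
            raise ValueError("non-MISSING joints must have z > 0")

    def mirrored(self) -> "Skeleton3D":
        """Reflect through the x=0 plane, swapping left/right joints."""
        j = self.joints[MIRROR_INDEX].copy()
        j[:, 0] = -j[:, 0]
        return Skeleton3D(self.timestamp, j)


def denormalize_landmark(u: float, v: float,
                         intr: CameraIntrinsics) -> tuple[int, int]:
    """Map normalized (u, v) to an integer pixel (i=row, j=column).

    Rounded half-up, then clamped to the valid pixel range (u = 1.0 maps to
    the last column, not one past it).
    """
    if not (0 <= u <= 1 and 0 <= v <= 1):
        raise LandmarkValidationError(
            f"normalized coordinates outside [0, 1]: ({u}, {v})")
    j = int(min(round_half_up(u * intr.width), intr.width - 1))
    i = int(min(round_half_up(v * intr.height), intr.height - 1))
    return i, j


def build_skeleton(frame: LandmarkFrame, depth: DepthFrame,
                   intr: CameraIntrinsics,
                   min_visibility: float = 0.5) -> Skeleton3D:
    """Assemble one metric skeleton from landmarks + depth + intrinsics."""
    joints = np.full((N_LANDMARKS, 3), MISSING)
    for k in range(N_LANDMARKS):
        u, v, vis = frame.landmarks[k]
        if vis < min_visibility:
            continue
        i, j = denormalize_landmark(u, v, intr)
        z = lookup_depth(depth, i, j, intr)
        if np.isnan(z):
            continue
        joints[k] = backproject_pixel(i, j, z, intr)
    return Skeleton3D(frame.timestamp, joints)


def stack_sequence(seq) -> tuple[np.ndarray, np.ndarray]:
    """Stack a skeleton sequence into ``(t (T,), joints (T, 33, 3))``."""
    t = np.array([s.timestamp for s in seq], dtype=float)
    joints = np.stack([s.joints for s in seq]) if seq else \
        np.empty((0, N_LANDMARKS, 3))
    return t, joints


def _fill_short_gaps(t: np.ndarray, x: np.ndarray, max_gap: float) -> np.ndarray:
    """Linearly interpolate NaN runs no longer than ``max_gap`` seconds."""
    x = x.copy()
    bad = ~np.isfinite(x)
    if not bad.any() or bad.all():
        return x
    idx = np.flatnonzero(bad)
    # contiguous NaN runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(x):
            continue  # leading/trailing gaps are not extrapolated
        if t[hi] - t[lo] > max_gap:
            continue
        x[run] = np.interp(t[run], [t[lo], t[hi]], [x[lo], x[hi]])
    return x


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centered running median; window shrinks at the borders."""
    n = len(x)
    r = window // 2
    out = np.empty(n)
    for k in range(n):
        seg = x[max(0, k - r):k + r + 1]
        finite = seg[np.isfinite(seg)]
        out[k] = np.median(finite) if finite.size else MISSING
    return out


def smooth_skeleton_sequence(seq, window: int = 5,
                             max_gap: float = 0.5) -> list:
    """Temporally denoise a skeleton sequence.

    Per joint and coordinate: MISSING runs bridged by neighbors no more
    than ``max_gap`` seconds apart are linearly interpolated (longer
    occlusions stay MISSING so downstream series show gaps rather than
    fabricated data), then a centered running median of odd width
    ``window`` suppresses single-frame depth spikes.  ``window=1`` applies
    no median.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    t, joints = stack_sequence(seq)
    if len(seq) == 0:
        return []
    out = np.empty_like(joints)
    for k in range(N_LANDMARKS):
        for c in range(3):
            x = _fill_short_gaps(t, joints[:, k, c], max_gap)
            out[:, k, c] = x if window == 1 else _running_median(x, window)
    return [Skeleton3D(t[f], out[f]) for f in range(len(seq))]


def pair_frames(landmark_frames, depth_frames, fps: float):
    """Pair landmark and depth frames by nearest timestamp.

    The match tolerance is half a frame period, 1 / (2 * fps); unmatched
    landmark frames are dropped with a logged warning.
    """
    tol = 1.0 / (2.0 * fps)
    dts = [d.timestamp for d in depth_frames]
    pairs = []
    for lf in landmark_frames:
        pos = bisect.bisect_left(dts, lf.timestamp)
        best = min((c for c in (pos - 1, pos, pos + 1)
                    if 0 <= c < len(dts)),
                   key=lambda c: abs(dts[c] - lf.timestamp), default=None)
        if best is None or abs(dts[best] - lf.timestamp) > tol:
            log.warning("no depth frame within %.4f s of t=%.4f; dropped",
                        tol, lf.timestamp)
            continue
        pairs.append((lf, depth_frames[best]))
    return pairs


def build_skeleton_sequence(landmark_frames, depth_frames,
                            intr: CameraIntrinsics,
                            min_visibility: float = 0.5,
                            fps: float | None = None,
                            smooth_window: int = 5) -> list:
    """Full extraction pipeline: pair, back-project, smooth.

    When ``fps`` is None it is estimated from the landmark timestamps.
    ``smooth_window=1`` disables smoothing.
    """
    if fps is None:
        ts = [lf.timestamp for lf in landmark_frames]
        fps = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 30.0
    pairs = pair_frames(landmark_frames, depth_frames, fps)
    seq = [build_skeleton(lf, df, intr, min_visibility) for lf, df in pairs]
    return smooth_skeleton_sequence(seq, window=smooth_window)
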