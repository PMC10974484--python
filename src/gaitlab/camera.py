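"""Pinhole camera model: depth lookup, back-projection and forward projection.

An RGB-D sensor delivers, for every pixel ``(i, j)`` (row, column, 0-based),
a depth reading ``z = depth(i, j)`` along the optical axis.  With the
intrinsic calibration ``fx, fy, cx, cy`` the pixel is lifted into a metric
3D point in the camera reference frame::

    x = (j - cx) * z / fx
    y = (i - cy) * z / fy
    z = depth(i, j)

Axes follow the standard pinhole convention: x right, y down, z forward
along the optical axis.  ``project_point`` is the exact algebraic inverse
and is what the synthetic rig uses to render known skeletons back into
pixel/depth space.

Missing depth is encoded as NaN throughout the package (``MISSING``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from .errors import BehindCameraError, InvalidDepthError

#: Sentinel for an unavailable measurement (depth hole, occluded joint, ...).
MISSING: float = float("nan")


def is_missing(value) -> bool:
    """True when *value* is the MISSING sentinel (NaN) or contains one."""
    return bool(np.any(np.isnan(value)))


class Point3D(NamedTuple):
    """A metric 3D point in the camera frame (x right, y down, z forward)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics plus the depth-unit scale.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Optical center (column, row) in pixels.
    width, height : int
        Image size in columns and rows.
    depth_scale : float
        Multiplier converting stored depth units to meters.  The default
        0.001 corresponds to 16-bit millimeter rasters.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("optical center must lie inside the image")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]), fy=float(d["fy"]),
            cx=float(d["cx"]), cy=float(d["cy"]),
            width=int(d["width"]), height=int(d["height"]),
            depth_scale=float(d.get("depth_scale", 0.001)),
        )

    @classmethod
    def from_file(cls, path) -> "CameraIntrinsics":
        """Load intrinsics from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


#: Intrinsics used by the synthetic rig and the round-trip property suites.
REFERENCE_INTRINSICS = CameraIntrinsics(
    fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480,
    depth_scale=0.001,
)


@dataclass
class DepthFrame:
    """One timestamped depth raster in stored (pre-scale) units.

    A raster value of 0 marks an invalid pixel (sensor dropout).
    """

    timestamp: float
    raster: np.ndarray

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("depth raster must be 2-D (height x width)")
        if np.any(self.raster < 0):
            raise ValueError("depth raster values must be non-negative")


def lookup_depth(frame: DepthFrame, i: int, j: int,
                 intr: CameraIntrinsics, fill_window: int = 5) -> float:
    """Depth in meters at pixel ``(i, j)``, with dropout fill.

    If the raster value is 0 (invalid), the median of the positive values
    in the ``fill_window`` x ``fill_window`` neighborhood is used instead;
    if the whole neighborhood is invalid, MISSING (NaN) is returned.
    Single-pixel dropout is common on structured-light RGB-D sensors, so a
    small median fill recovers the joint depth without smearing edges.
    """
    h, w = frame.raster.shape
    if not (0 <= i < h and 0 <= j < w):
        raise IndexError(f"pixel ({i}, {j}) outside {h}x{w} raster")
    v = frame.raster[i, j]
    if v > 0:
        return float(v) * intr.depth_scale
    r = fill_window // 2
    win = frame.raster[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1]
    pos = win[win > 0]
    if pos.size == 0:
        return MISSING
    return float(np.median(pos)) * intr.depth_scale


def backproject_pixel(i: float, j: float, z: float,
                      intr: CameraIntrinsics) -> Point3D:
    """Lift pixel ``(i, j)`` at depth ``z`` (meters) into the camera frame."""
    if not z > 0:
        raise InvalidDepthError(f"depth must be positive, got {z}")
    x = (j - intr.cx) * z / intr.fx
    y = (i - intr.cy) * z / intr.fy
    return Point3D(x, y, z)


def project_point(p, intr: CameraIntrinsics):
    """Project a camera-frame point to ``(i, j, stored_depth)``.

    Exact inverse of :func:`backproject_pixel`; ``i`` and ``j`` are returned
    as floats — rounding to integer pixels happens when rasterizing.  The
    stored depth is ``round(z / depth_scale)`` (e.g. millimeters for the
    default scale).
    """
    x, y, z = float(p[0]), float(p[1]), float(p[2])
    if not z > 0:
        raise BehindCameraError(f"cannot project point with z={z}")
    j = intr.fx * x / z + intr.cx
    i = intr.fy * y / z + intr.cy
    stored = int(round(z / intr.depth_scale))
    return i, j, stored


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with ties away from the floor (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
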