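"""Session bundle I/O: depth rasters, landmark streams, intrinsics, index.

A recorded (or simulated) session is a directory::

    session/
      intrinsics.json          # fx, fy, cx, cy, width, height, depth_scale
      landmarks.jsonl          # one {"t": s, "lm": [[u, v, vis] x 33]} per line
      frames.csv               # frame_index, timestamp_s
      depth_000000.pgm ...     # one 16-bit PGM (millimeters) per frame
      meta.json                # optional subject / scenario annotations

Depth rasters use binary 16-bit PGM (P5, maxval 65535, big-endian sample
order per the Netpbm spec) — lossless, ubiquitous, and trivial to parse.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraIntrinsics, DepthFrame
from .errors import SessionFormatError
from .skeleton import LandmarkFrame, N_LANDMARKS

DEPTH_PATTERN = "depth_{:06d}.pgm"


# ----------------------------------------------------------------------
# 16-bit PGM codec

def write_pgm16(path, raster: np.ndarray) -> None:
    raster = np.asarray(raster)
    if raster.dtype != np.uint16:
        if np.any(raster < 0) or np.any(raster > 65535):
            raise ValueError("raster out of uint16 range")
        raster = raster.astype(np.uint16)
    h, w = raster.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n65535\n".encode("ascii"))
        fh.write(raster.astype(">u2").tobytes())


def read_pgm16(path) -> np.ndarray:
    data = Path(path).read_bytes()
    m = re.match(rb"P5\s+(?:#[^\n]*\n\s*)*(\d+)\s+(\d+)\s+(\d+)\s", data)
    if not m:
        raise SessionFormatError(f"{path}: not a binary PGM")
    w, h, maxval = (int(g) for g in m.groups())
    if maxval > 65535:
        raise SessionFormatError(f"{path}: maxval {maxval} > 65535")
    dtype = ">u2" if maxval > 255 else np.uint8
    pixels = np.frombuffer(data, dtype=dtype, offset=m.end(),
                           count=w * h)
    return pixels.reshape(h, w).astype(np.uint16)


# ----------------------------------------------------------------------
# Landmark stream (JSON Lines)

def write_landmarks_jsonl(path, frames) -> None:
    with open(path, "w") as fh:
        for f in frames:
            fh.write(json.dumps(
                {"t": f.timestamp, "lm": f.landmarks.tolist()}) + "\n")


def read_landmarks_jsonl(path) -> list[LandmarkFrame]:
    frames = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                lm = np.asarray(obj["lm"], dtype=float)
                if lm.shape != (N_LANDMARKS, 3):
                    raise ValueError(
                        f"expected {N_LANDMARKS} landmarks of (u, v, vis), "
                        f"got shape {lm.shape} — multi-person or truncated "
                        "input is not supported")
                frames.append(LandmarkFrame(float(obj["t"]), lm))
            except SessionFormatError:
                raise
            except Exception as exc:
                raise SessionFormatError(
                    f"{path}:{lineno}: {exc}") from exc
    return frames


def read_landmarks_csv(path) -> list[LandmarkFrame]:
    """CSV alternative: columns t, lm0_u, lm0_v, lm0_vis, ..., lm32_vis."""
    import pandas as pd
    df = pd.read_csv(path)
    frames = []
    for _, row in df.iterrows():
        lm = np.array([[row[f"lm{k}_u"], row[f"lm{k}_v"], row[f"lm{k}_vis"]]
                       for k in range(N_LANDMARKS)])
        frames.append(LandmarkFrame(float(row["t"]), lm))
    return frames


# ----------------------------------------------------------------------
# Bundle

@dataclass
class SessionBundle:
    """Paths and metadata of one recorded or simulated session."""

    root: Path
    landmarks_path: Path
    intrinsics_path: Path
    index_path: Path
    depth_paths: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def load_intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics.from_file(self.intrinsics_path)

    def load_landmarks(self) -> list[LandmarkFrame]:
        return read_landmarks_jsonl(self.landmarks_path)

    def load_depth_frames(self) -> list[DepthFrame]:
        index = self.load_index()
        return [DepthFrame(ts, read_pgm16(p))
                for (_, ts), p in zip(index, self.depth_paths)]

    def load_index(self) -> list[tuple[int, float]]:
        with open(self.index_path) as fh:
            rows = list(csv.DictReader(fh))
        return [(int(r["frame_index"]), float(r["timestamp_s"]))
                for r in rows]


def write_session(out_dir, landmark_frames, depth_frames,
                  intr: CameraIntrinsics, meta: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    intr.to_file(out / "intrinsics.json")
    write_landmarks_jsonl(out / "landmarks.jsonl", landmark_frames)
    with open(out / "frames.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame_index", "timestamp_s"])
        for k, df in enumerate(depth_frames):
            wr.writerow([k, repr(float(df.timestamp))])
            write_pgm16(out / DEPTH_PATTERN.format(k), df.raster)
    if meta:
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_session(path) -> SessionBundle:
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"no session directory at {root}")
    bundle = SessionBundle(
        root=root,
        landmarks_path=root / "landmarks.jsonl",
        intrinsics_path=root / "intrinsics.json",
        index_path=root / "frames.csv",
        depth_paths=sorted(root.glob("depth_*.pgm")),
    )
    meta_path = root / "meta.json"
    if meta_path.exists():
        bundle.meta = json.loads(meta_path.read_text())
    for p in (bundle.landmarks_path, bundle.intrinsics_path,
              bundle.index_path):
        if not p.exists():
            raise SessionFormatError(f"missing session component: {p.name}")
    return bundle


@dataclass
class ValidationReport:
    ok: bool
    issues: list


def validate_session(bundle: SessionBundle) -> ValidationReport:
    """Cross-check every bundle component; list all inconsistencies."""
    issues: list[str] = []
    try:
        intr = bundle.load_intrinsics()
    except Exception as exc:
        return ValidationReport(False, [f"intrinsics: {exc}"])
    try:
        landmarks = bundle.load_landmarks()
    except Exception as exc:
        return ValidationReport(False, [str(exc)])
    index = bundle.load_index()
    if len(index) != len(bundle.depth_paths):
        issues.append(f"frames.csv lists {len(index)} frames but "
                      f"{len(bundle.depth_paths)} depth rasters exist")
    if len(landmarks) != len(index):
        issues.append(f"{len(landmarks)} landmark frames vs "
                      f"{len(index)} indexed depth frames")
    ts = [t for _, t in index]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        issues.append("frames.csv timestamps are not strictly increasing")
    lts = [f.timestamp for f in landmarks]
    if any(b <= a for a, b in zip(lts, lts[1:])):
        issues.append("landmark timestamps are not strictly increasing")
    for p in bundle.depth_paths[:3]:  # spot-check raster geometry
        raster = read_pgm16(p)
        if raster.shape != (intr.height, intr.width):
            issues.append(f"{p.name}: raster {raster.shape} does not match "
                          f"intrinsics {(intr.height, intr.width)}")
    return ValidationReport(not issues, issues)


def extract_skeletons(session, min_visibility: float = 0.5,
                      smooth_window: int = 5) -> list:
    """Run the extraction pipeline on a session directory or bundle."""
    from .skeleton import build_skeleton_sequence
    bundle = session if isinstance(session, SessionBundle) \
        else read_session(session)
    return build_skeleton_sequence(
        bundle.load_landmarks(), bundle.load_depth_frames(),
        bundle.load_intrinsics(),
        min_visibility=min_visibility,
        fps=bundle.meta.get("fps"),
        smooth_window=smooth_window)
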