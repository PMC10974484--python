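"""Script-driven articulated-skeleton simulator.

The simulator is the package's ground-truth engine: a scenario script
(stance, forced sway, sit-to-stand, straight or curved walk) is turned
into a deterministic kinematic 33-joint stick body 2-4.5 m in front of
the camera, and each true pose is rendered *through the same camera model
the extraction pipeline inverts* — joints are forward-projected with the
reference intrinsics, rasterized as small depth discs into a 16-bit
millimeter raster, and re-normalized into [0,1] landmark coordinates,
optionally with seeded Gaussian depth noise and landmark jitter.  The
rendered streams are byte-compatible with recorded sessions, so every
fixture is indistinguishable from real input, and the scripted kinematics
provide analytic ground truth for every parameter.

All randomness flows from the single recorded seed; equal scripts render
bit-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .camera import REFERENCE_INTRINSICS, CameraIntrinsics, DepthFrame, \
    project_point, round_half_up
from .errors import ScenarioError
from .skeleton import LandmarkFrame, Skeleton3D, N_LANDMARKS
from . import skeleton as sk

SCENARIO_KINDS = ("static_stance", "forced_sway", "sit_to_stand",
                  "walk", "curved_walk")


@dataclass(frozen=True)
class Anthropometry:
    """Body dimensions (meters); segment proportions scale with stature."""

    stature: float = 1.70
    shoulder_width: float = 0.40
    hip_width: float = 0.30

    # standing joint heights above the ground, as stature fractions
    @property
    def ankle_h(self): return 0.050 * self.stature
    @property
    def knee_h(self): return 0.285 * self.stature
    @property
    def hip_h(self): return 0.530 * self.stature
    @property
    def shoulder_h(self): return 0.818 * self.stature
    @property
    def nose_h(self): return 0.930 * self.stature
    @property
    def trunk_len(self): return self.shoulder_h - self.hip_h
    @property
    def upper_arm(self): return 0.186 * self.stature
    @property
    def forearm(self): return 0.146 * self.stature


@dataclass
class ScenarioScript:
    """Declarative description of one synthetic capture.

    Kind-specific controls are ignored by the other kinds.  ``start_depth``
    and ``heel_separation`` default per kind (walks start at 4.5 m so the
    whole body stays in frame down to ~1.8 m; stationary scenarios sit at
    3 m; resting heel separation equals the hip width).
    """

    kind: str = "static_stance"
    duration: float = 10.0
    fps: float = 30.0
    seed: int = 0
    anthropometry: Anthropometry = field(default_factory=Anthropometry)
    camera_height: float = 0.8        # m above the ground plane
    start_depth: float | None = None  # m from the camera
    heel_separation: float | None = None
    # forced_sway / static_stance
    sway_amplitude_deg: float = 40.0
    sway_freq_hz: float = 0.5
    sway_jitter_deg: float = 0.0      # per-frame random shoulder roll (sd)
    # walk / curved_walk
    step_length: float = 0.45
    cadence: float = 1.5              # steps per second
    arm_swing: float = 0.10           # wrist fore-aft amplitude, m
    lateral_sway: float = 0.02        # hip side-to-side amplitude, m
    lateral_drift: float = 0.5        # curved_walk total lateral offset, m
    # sit_to_stand
    seated_tilt_deg: float = 120.0
    stand_lean_deg: float = 5.0
    elbow_pushoff_deg: float = 180.0  # 180 = arms stay extended
    # rendering noise
    depth_noise_sd: float = 0.01      # m
    landmark_jitter_px: float = 1.0
    occlusions: list = field(default_factory=list)  # [joint, t0, t1] triples

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        if self.duration <= 0:
            raise ScenarioError("duration must be positive")
        if self.fps < 10:
            raise ScenarioError("fps must be at least 10")
        a = self.anthropometry
        if isinstance(a, dict):
            a = Anthropometry(**a)
            self.anthropometry = a
        if min(a.stature, a.shoulder_width, a.hip_width) <= 0:
            raise ScenarioError("anthropometry lengths must be positive")
        if self.start_depth is None:
            self.start_depth = 4.5 if self.kind in ("walk", "curved_walk") \
                else 3.0
        if self.heel_separation is None:
            self.heel_separation = a.hip_width

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioScript":
        d = dict(d)
        if "anthropometry" in d and isinstance(d["anthropometry"], dict):
            d["anthropometry"] = Anthropometry(**d["anthropometry"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioScript":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ----------------------------------------------------------------------
# Kinematics

def _rot2(vy: float, vz: float, deg: float) -> tuple[float, float]:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return vy * c - vz * s, vy * s + vz * c


def _standing_template(an: Anthropometry, ch: float, x0: float, z0: float,
                       heel_sep: float) -> np.ndarray:
    """Neutral standing pose facing the camera, (33, 3) camera-frame."""
    J = np.zeros((N_LANDMARKS, 3))
    y = lambda h: ch - h  # camera y (down) from height above ground
    sw2, hw2 = an.shoulder_width / 2, an.hip_width / 2
    hs2 = heel_sep / 2
    arm_x = sw2 + 0.03  # arms hang slightly lateral of the torso

    def put(idx, dx, h, dz=0.0):
        J[idx] = (x0 + dx, y(h), z0 + dz)

    # head cluster (left = +x)
    put(sk.NOSE, 0.0, an.nose_h, -0.08)
    for side, s in (("left", +1), ("right", -1)):
        base = 1 if side == "left" else 4
        put(base + 0, s * 0.02, an.nose_h + 0.04, -0.06)   # eye inner
        put(base + 1, s * 0.03, an.nose_h + 0.04, -0.06)   # eye
        put(base + 2, s * 0.045, an.nose_h + 0.04, -0.06)  # eye outer
    put(7, +0.08, an.nose_h + 0.02, 0.0)    # ears
    put(8, -0.08, an.nose_h + 0.02, 0.0)
    put(9, +0.02, an.nose_h - 0.04, -0.07)  # mouth corners
    put(10, -0.02, an.nose_h - 0.04, -0.07)
    # torso and arms
    elbow_h = an.shoulder_h - an.upper_arm
    wrist_h = elbow_h - an.forearm
    for idx_l, idx_r, dx, h in (
            (sk.LEFT_SHOULDER, sk.RIGHT_SHOULDER, sw2, an.shoulder_h),
            (sk.LEFT_ELBOW, sk.RIGHT_ELBOW, arm_x - 0.02, elbow_h),
            (sk.LEFT_WRIST, sk.RIGHT_WRIST, arm_x, wrist_h),
            (17, 18, arm_x + 0.01, wrist_h - 0.08),   # pinky
            (19, 20, arm_x - 0.01, wrist_h - 0.09),   # index
            (21, 22, arm_x - 0.02, wrist_h - 0.06),   # thumb
            (sk.LEFT_HIP, sk.RIGHT_HIP, hw2, an.hip_h)):
        put(idx_l, +dx, h)
        put(idx_r, -dx, h)
    # legs: knees between hip and ankle laterally (splayed wide stances)
    knee_x = 0.5 * (hw2 + hs2)
    for idx_l, idx_r, dx, h, dz in (
            (sk.LEFT_KNEE, sk.RIGHT_KNEE, knee_x, an.knee_h, 0.0),
            (sk.LEFT_ANKLE, sk.RIGHT_ANKLE, hs2, an.ankle_h, 0.0),
            (sk.LEFT_HEEL, sk.RIGHT_HEEL, hs2, 0.03, 0.07),
            (sk.LEFT_FOOT_INDEX, sk.RIGHT_FOOT_INDEX, hs2, 0.02, -0.15)):
        put(idx_l, +dx, h, dz)
        put(idx_r, -dx, h, dz)
    return J


_UPPER_BODY = np.arange(0, 23)  # head, arms, shoulders


def _apply_roll(J: np.ndarray, deg: float) -> np.ndarray:
    """Tilt the upper body by ``deg`` about the hip midpoint (frontal plane).

    The shoulder line's inclination to the horizontal then equals |deg|.
    """
    if deg == 0.0:
        return J
    J = J.copy()
    pivot = 0.5 * (J[sk.LEFT_HIP] + J[sk.RIGHT_HIP])
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    dx = J[_UPPER_BODY, 0] - pivot[0]
    dy = J[_UPPER_BODY, 1] - pivot[1]
    J[_UPPER_BODY, 0] = pivot[0] + c * dx - s * dy
    J[_UPPER_BODY, 1] = pivot[1] + s * dx + c * dy
    return J


def _jitter_roll(script: ScenarioScript, frame_idx: int) -> float:
    rng = np.random.default_rng([script.seed, 7, frame_idx])
    return float(rng.normal(0.0, script.sway_jitter_deg))


def _sts_progress(script: ScenarioScript, t: float) -> float:
    """Smoothstep 0->1 over the middle third of the duration."""
    third = script.duration / 3.0
    q = min(max((t - third) / third, 0.0), 1.0)
    return q * q * (3.0 - 2.0 * q)


def sts_trunk_tilt(script: ScenarioScript, t: float) -> float:
    """True shoulder-hip-knee angle (deg) of the sit-to-stand script."""
    stand = 180.0 - script.stand_lean_deg
    return script.seated_tilt_deg + \
        (stand - script.seated_tilt_deg) * _sts_progress(script, t)


def sts_elbow_angle(script: ScenarioScript, t: float) -> float:
    """True shoulder-elbow-wrist interior angle (deg); dips at push-off."""
    bump = math.sin(math.pi * _sts_progress(script, t)) ** 2
    return 180.0 - (180.0 - script.elbow_pushoff_deg) * bump


def _pose_sit_to_stand(script: ScenarioScript, t: float) -> np.ndarray:
    an, ch = script.anthropometry, script.camera_height
    z0 = script.start_depth
    s = _sts_progress(script, t)
    alpha = sts_trunk_tilt(script, t)
    beta = sts_elbow_angle(script, t)
    J = _standing_template(an, ch, 0.0, z0, script.heel_separation)
    hw2 = an.hip_width / 2
    # hip and knee interpolate between seated and standing placements;
    # ankles stay planted.
    hip_h = 0.48 + (an.hip_h - 0.48) * s
    hip_dz = 0.30 * (1.0 - s)
    knee_dz = -0.05 * (1.0 - s)
    for side, sign in (("l", +1), ("r", -1)):
        hip_i = sk.LEFT_HIP if sign > 0 else sk.RIGHT_HIP
        knee_i = sk.LEFT_KNEE if sign > 0 else sk.RIGHT_KNEE
        sho_i = sk.LEFT_SHOULDER if sign > 0 else sk.RIGHT_SHOULDER
        elb_i = sk.LEFT_ELBOW if sign > 0 else sk.RIGHT_ELBOW
        wri_i = sk.LEFT_WRIST if sign > 0 else sk.RIGHT_WRIST
        hip = np.array([sign * hw2, ch - hip_h, z0 + hip_dz])
        knee = np.array([sign * hw2, ch - an.knee_h, z0 + knee_dz])
        J[hip_i], J[knee_i] = hip, knee
        # trunk direction: knee->hip ray rotated by alpha in the sagittal
        # plane, upward branch
        u = (knee - hip)[1:]
        u = u / np.linalg.norm(u)
        cand = [_rot2(u[0], u[1], a) for a in (alpha, -alpha)]
        dy, dz = min(cand, key=lambda v: v[0])  # smaller camera-y = higher
        trunk = np.array([0.0, dy, dz])
        J[sho_i] = hip + an.trunk_len * trunk
        J[sho_i, 0] = sign * an.shoulder_width / 2
        # arms: upper arm along the trunk, forearm at interior angle beta
        arm_x = sign * (an.shoulder_width / 2 + 0.03)
        J[elb_i] = J[sho_i] + an.upper_arm * (-trunk)
        J[elb_i, 0] = arm_x - sign * 0.02
        fc = [_rot2(-dy, -dz, a) for a in (180 - beta, beta - 180)]
        fy, fz = min(fc, key=lambda v: v[1])  # push-off swings forward (-z)
        J[wri_i] = J[elb_i] + an.forearm * np.array([0.0, fy, fz])
        J[wri_i, 0] = arm_x
        # hand cluster follows the wrist
        for h_i in ((17, 19, 21) if sign > 0 else (18, 20, 22)):
            J[h_i] = J[wri_i] + 0.07 * np.array([0.0, fy, fz])
            J[h_i, 0] = arm_x
    # head follows the trunk
    sho_mid = 0.5 * (J[sk.LEFT_SHOULDER] + J[sk.RIGHT_SHOULDER])
    hip_mid = 0.5 * (J[sk.LEFT_HIP] + J[sk.RIGHT_HIP])
    trunk = (sho_mid - hip_mid) / np.linalg.norm(sho_mid - hip_mid)
    head_base = sho_mid + (an.nose_h - an.shoulder_h) * trunk
    nose_ref = np.array([0.0, ch - an.nose_h, z0])
    for idx in range(0, 11):
        J[idx] = head_base + (J[idx] - nose_ref)
    return J


def _pose_walk(script: ScenarioScript, t: float) -> np.ndarray:
    an = script.anthropometry
    speed = script.cadence * script.step_length / 2.0
    phase = math.sin(math.pi * script.cadence * t)
    zc = script.start_depth - speed * t
    x0 = script.lateral_sway * math.sin(math.pi * script.cadence * t / 2.0)
    if script.kind == "curved_walk":
        x0 += script.lateral_drift * (t / script.duration) ** 2
    J = _standing_template(an, script.camera_height, x0, zc,
                           script.heel_separation)
    # ankles (and feet) alternate fore-aft by half a step length each
    dz = 0.5 * script.step_length * phase
    for idx in (sk.LEFT_ANKLE, sk.LEFT_HEEL, sk.LEFT_FOOT_INDEX):
        J[idx, 2] += dz
    for idx in (sk.RIGHT_ANKLE, sk.RIGHT_HEEL, sk.RIGHT_FOOT_INDEX):
        J[idx, 2] -= dz
    # arm swing opposes the ipsilateral foot
    dzw = script.arm_swing * phase
    for idx in (sk.LEFT_WRIST, 17, 19, 21):
        J[idx, 2] -= dzw
    for idx in (sk.RIGHT_WRIST, 18, 20, 22):
        J[idx, 2] += dzw
    return J


def pose_at(script: ScenarioScript, t: float) -> Skeleton3D:
    """True, noise-free pose of the scripted body at time ``t``."""
    if not (0.0 <= t <= script.duration):
        raise ScenarioError(
            f"t={t} outside [0, {script.duration}]")
    if script.kind == "static_stance":
        J = _standing_template(script.anthropometry, script.camera_height,
                               0.0, script.start_depth,
                               script.heel_separation)
        if script.sway_jitter_deg > 0:
            k = int(round(t * script.fps))
            J = _apply_roll(J, _jitter_roll(script, k))
    elif script.kind == "forced_sway":
        J = _standing_template(script.anthropometry, script.camera_height,
                               0.0, script.start_depth,
                               script.heel_separation)
        roll = script.sway_amplitude_deg * math.sin(
            2.0 * math.pi * script.sway_freq_hz * t)
        J = _apply_roll(J, roll)
    elif script.kind == "sit_to_stand":
        J = _pose_sit_to_stand(script, t)
    else:  # walk / curved_walk
        J = _pose_walk(script, t)
    return Skeleton3D(t, J)


# ----------------------------------------------------------------------
# Ground truth

@dataclass
class GroundTruth:
    """Analytic per-scenario truth, derived from the script itself."""

    times: np.ndarray
    frames: list            # true noise-free Skeleton3D per frame
    targets: dict           # named truth series / scalars


def _true_series(frames, fn) -> np.ndarray:
    """Evaluate a geometric parameter on the true (noise-free) poses.

    The true poses come from the script's kinematics, so this is still
    script-derived truth — the rendered streams never enter here.  It is
    needed for the three-joint angles whose exact value depends on the
    full 3D body build (e.g. shoulders sit wider than hips, so the true
    shoulder-hip-knee angle is slightly below the scripted sagittal one).
    """
    return fn(frames).v


def ground_truth(script: ScenarioScript) -> GroundTruth:
    from . import parameters as par  # deferred: parameters imports nothing here
    times = script.frame_times
    frames = [pose_at(script, t) for t in times]
    targets: dict = {"seed": script.seed}
    if script.kind == "static_stance":
        if script.sway_jitter_deg > 0:
            rolls = np.array([_jitter_roll(script, int(round(t * script.fps)))
                              for t in times])
            targets["trunk_swing_deg"] = np.abs(rolls)
        else:
            targets["trunk_swing_deg"] = np.zeros_like(times)
        targets["heel_separation_m"] = script.heel_separation
        targets["trunk_tilt_mean_deg"] = _true_series(
            frames, par.trunk_tilt_mean)
    elif script.kind == "forced_sway":
        targets["trunk_swing_deg"] = np.abs(
            script.sway_amplitude_deg *
            np.sin(2 * np.pi * script.sway_freq_hz * times))
    elif script.kind == "sit_to_stand":
        targets["trunk_tilt_mean_deg"] = _true_series(
            frames, par.trunk_tilt_mean)
        # both sides are scripted symmetrically: one truth series serves both
        targets["arm_support_deg"] = _true_series(
            frames, lambda s: par.arm_support_angle(s, "left"))
        targets["arm_support_used"] = script.elbow_pushoff_deg < 100.0
    else:
        targets["speed_mps"] = script.cadence * script.step_length / 2.0
        targets["step_length_m"] = script.step_length
        targets["trunk_swing_deg"] = np.zeros_like(times)
        x0 = script.lateral_sway * np.sin(
            np.pi * script.cadence * times / 2.0)
        if script.kind == "curved_walk":
            x0 = x0 + script.lateral_drift * (times / script.duration) ** 2
        targets["lateral_m"] = x0
    return GroundTruth(times, frames, targets)


# ----------------------------------------------------------------------
# Rendering

_DISC_RADIUS = 4
_dy, _dx = np.mgrid[-_DISC_RADIUS:_DISC_RADIUS + 1,
                    -_DISC_RADIUS:_DISC_RADIUS + 1]
_DISC = np.flatnonzero((_dy ** 2 + _dx ** 2).ravel() <= _DISC_RADIUS ** 2)
_DISC_DY, _DISC_DX = _dy.ravel()[_DISC], _dx.ravel()[_DISC]


@dataclass
class RenderResult:
    landmarks: list          # LandmarkFrame stream
    depths: list             # DepthFrame stream
    intrinsics: CameraIntrinsics
    truth: GroundTruth


def _occluded(script: ScenarioScript, joint: int, t: float) -> bool:
    return any(j == joint and t0 <= t <= t1
               for j, t0, t1 in script.occlusions)


def render(script: ScenarioScript,
           intr: CameraIntrinsics = REFERENCE_INTRINSICS) -> RenderResult:
    """Render the script into landmark + depth streams through ``intr``.

    Each true joint is forward-projected; a depth disc of radius 4 px
    (nearer joints win on overlap) gives the dropout-fill logic support;
    seeded Gaussian depth noise and landmark jitter are added per joint.
    """
    truth = ground_truth(script)
    landmarks, depths = [], []
    for k, t in enumerate(truth.times):
        J = truth.frames[k].joints
        rng = np.random.default_rng([script.seed, 11, k])
        depth_noise = rng.normal(0.0, script.depth_noise_sd, N_LANDMARKS) \
            if script.depth_noise_sd > 0 else np.zeros(N_LANDMARKS)
        jitter = rng.normal(0.0, script.landmark_jitter_px,
                            (N_LANDMARKS, 2)) \
            if script.landmark_jitter_px > 0 else np.zeros((N_LANDMARKS, 2))
        raster = np.zeros((intr.height, intr.width), dtype=np.uint16)
        lm = np.zeros((N_LANDMARKS, 3))
        ij = np.empty((N_LANDMARKS, 2))
        for n in range(N_LANDMARKS):
            i, j, _ = project_point(J[n], intr)  # raises behind camera
            ij[n] = i, j
        # far-to-near so nearer discs overwrite farther ones
        for n in np.argsort(-J[:, 2]):
            z_noisy = max(J[n, 2] + depth_noise[n], intr.depth_scale)
            stored = int(round(z_noisy / intr.depth_scale))
            ci, cj = int(round_half_up(ij[n, 0])), int(round_half_up(ij[n, 1]))
            ii, jj = ci + _DISC_DY, cj + _DISC_DX
            keep = (ii >= 0) & (ii < intr.height) & \
                   (jj >= 0) & (jj < intr.width)
            raster[ii[keep], jj[keep]] = min(stored, 65535)
        for n in range(N_LANDMARKS):
            u = (ij[n, 1] + jitter[n, 0]) / intr.width
            v = (ij[n, 0] + jitter[n, 1]) / intr.height
            vis = 0.0 if _occluded(script, n, t) else 1.0
            lm[n] = (min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0), vis)
        landmarks.append(LandmarkFrame(t, lm))
        depths.append(DepthFrame(t, raster))
    return RenderResult(landmarks, depths, intr, truth)


def render_to_session(script: ScenarioScript, out_dir,
                      intr: CameraIntrinsics = REFERENCE_INTRINSICS
                      ) -> RenderResult:
    """Render and write a session bundle indistinguishable from a capture."""
    from .session import write_session
    result = render(script, intr)
    meta = {"scenario": script.to_dict(), "fps": script.fps,
            "seed": script.seed}
    write_session(out_dir, result.landmarks, result.depths, intr, meta)
    return result


def simulate_and_extract(script: ScenarioScript, min_visibility: float = 0.5,
                         smooth_window: int = 5):
    """Full loop in memory: render, then run the extraction pipeline.

    Returns ``(skeleton sequence, GroundTruth)`` — the workhorse of the
    parameter-recovery property suites.
    """
    result = render(script)
    seq = sk.build_skeleton_sequence(
        result.landmarks, result.depths, result.intrinsics,
        min_visibility=min_visibility, fps=script.fps,
        smooth_window=smooth_window)
    return seq, result.truth
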