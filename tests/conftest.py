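import numpy as np
import pytest

from gaitlab import REFERENCE_INTRINSICS, Skeleton3D
from gaitlab.simulate import ScenarioScript, simulate_and_extract


@pytest.fixture(scope="session")
def intr():
    return REFERENCE_INTRINSICS


def make_skeleton(joints=None, t=0.0):
    """Skeleton with selected joints set; everything else at a dummy point.

    ``joints`` maps landmark index -> (x, y, z).
    """
    J = np.tile(np.array([0.0, 0.0, 9.0]), (33, 1))
    for idx, p in (joints or {}).items():
        J[idx] = p
    return Skeleton3D(t, J)


@pytest.fixture(scope="session")
def sway_clean():
    """Forced sway 40 deg at 0.5 Hz, rendered without noise, extracted."""
    script = ScenarioScript(kind="forced_sway", duration=10, fps=30,
                            depth_noise_sd=0.0, landmark_jitter_px=0.0,
                            seed=101)
    return simulate_and_extract(script)


@pytest.fixture(scope="session")
def static_jittered():
    """Upright stance, 1 deg shoulder jitter, default rendering noise."""
    script = ScenarioScript(kind="static_stance", duration=10, fps=30,
                            sway_jitter_deg=1.0, seed=102)
    return simulate_and_extract(script)


@pytest.fixture(scope="session")
def sts_pushoff_clean():
    """Sit-to-stand ending at 5 deg lean, 75 deg elbow push-off, no noise."""
    script = ScenarioScript(kind="sit_to_stand", duration=10, fps=30,
                            elbow_pushoff_deg=75.0,
                            depth_noise_sd=0.0, landmark_jitter_px=0.0,
                            seed=103)
    return simulate_and_extract(script)


@pytest.fixture(scope="session")
def walk_clean():
    """Straight walk, 0.45 m steps at 1.5 steps/s, 8 s, no noise."""
    script = ScenarioScript(kind="walk", duration=8, fps=30,
                            depth_noise_sd=0.0, landmark_jitter_px=0.0,
                            seed=104)
    return simulate_and_extract(script)


#: scenario scripts at default rendering noise for full-loop recovery.
NOISY_SCRIPTS = {
    "static_stance": ScenarioScript(kind="static_stance", duration=10,
                                    seed=7),
    "forced_sway": ScenarioScript(kind="forced_sway", duration=10, seed=7),
    "sit_to_stand": ScenarioScript(kind="sit_to_stand", duration=10,
                                   elbow_pushoff_deg=75.0, seed=7),
    "walk": ScenarioScript(kind="walk", duration=8, seed=7),
    "curved_walk": ScenarioScript(kind="curved_walk", duration=8, seed=7),
}


@pytest.fixture(scope="session")
def noisy_runs():
    return {kind: simulate_and_extract(script)
            for kind, script in NOISY_SCRIPTS.items()}
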