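import numpy as np
import pytest
from hypothesis import settings

from neurocard import (SimulationConfig, render_optical, simulate_monolayer)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def plane_sim():
    """A paced plane-wave recording with ground truth (default kinetics)."""
    cfg = SimulationConfig(regime="plane", frames=200, seed=11)
    return simulate_monolayer(cfg)


@pytest.fixture(scope="session")
def plane_video_clean(plane_sim):
    video, _ = plane_sim
    return render_optical(video, noise_sd=0.0, blur_sigma=0.0,
                          modality="voltage_like")


@pytest.fixture(scope="session")
def plane_video_noisy(plane_sim):
    video, _ = plane_sim
    return render_optical(video, noise_sd=0.02, blur_sigma=1.0,
                          modality="voltage_like", seed=11)


@pytest.fixture(scope="session")
def target_sim():
    """A focal (target-wave) recording with a known source location."""
    cfg = SimulationConfig(regime="target", frames=300, seed=5)
    return simulate_monolayer(cfg)


@pytest.fixture(scope="session")
def spiral_sim():
    """A single-spiral recording; truth holds one persistent rotor."""
    cfg = SimulationConfig(regime="single_spiral", frames=350, seed=3)
    return simulate_monolayer(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
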