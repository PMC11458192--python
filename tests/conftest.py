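import pytest

from gazesharp.atlas import build_default_atlas
from gazesharp.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def atlas():
    return build_default_atlas()


@pytest.fixture(scope="session")
def noiseless_study(atlas):
    """Small noiseless, ambiguity-free study: the pipeline must invert it exactly."""
    config = SimConfig(n_patients=4, duration_noise_sd_ms=0.0, ambiguity_rate=0.0, seed=42)
    truth, layout, streams = simulate_study(config, atlas)
    return config, truth, layout, streams


@pytest.fixture(scope="session")
def noisy_study(atlas):
    """Default study conditions at a reduced patient count."""
    config = SimConfig(n_patients=6, seed=123)
    truth, layout, streams = simulate_study(config, atlas)
    return config, truth, layout, streams
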