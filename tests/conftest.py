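import numpy as np
import pytest

from svheart import SimConfig, generate_speckle_frame


@pytest.fixture(scope="session")
def speckle_frame():
    """One seeded 256x256 fully developed speckle frame, grain 4 px."""
    return generate_speckle_frame((256, 256), 4.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_sim_config():
    """A small, fast simulation: 8 s of 64x64 video."""
    return SimConfig(duration_s=8.0, frame_shape=(64, 64), seed=7)
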