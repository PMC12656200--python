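import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One 400x400 synthetic canopy scene shared across tests."""
    from canopysense.synthetic import gen_canopy_scene

    rgb, truth = gen_canopy_scene(0.6, 0.3, width=400, height=400, seed=11)
    return rgb, truth
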