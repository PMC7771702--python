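import numpy as np
import pytest

from skullmark import synthetic as syn
from skullmark import experiments


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scene():
    """One rendered tiny-preset scene with exact annotations."""
    return syn.generate_scene(preset=syn.TINY, seed=7)


@pytest.fixture(scope="session")
def tiny_scenes():
    """A batch of 20 tiny scenes for detector statistics."""
    return [syn.generate_scene(preset=syn.TINY, seed=100 + i) for i in range(20)]


@pytest.fixture(scope="session")
def tiny_protocol():
    """The trained tiny-preset pipeline (shared by the slow end-to-end checks).

    50 scenes x 4 augmented copies = 200 training crops, 64-net,
    quarter-width network, 30 epochs, fixed seed.
    """
    return experiments.run_protocol(seed=1)
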