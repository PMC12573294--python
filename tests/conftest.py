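import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_map(rng):
    """A random 1x4x5x5 feature map."""
    return rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
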