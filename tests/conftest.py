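import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def checkerboard():
    """8x8 binary checkerboard: every horizontal neighbour pair differs by 1."""
    idx = np.add.outer(np.arange(8), np.arange(8))
    return (idx % 2).astype(float)
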