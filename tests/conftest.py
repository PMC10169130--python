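import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc32():
    """A centred disc of radius 10 on a 32x32 canvas."""
    yy, xx = np.mgrid[0:32, 0:32]
    return ((yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 100).astype(np.uint8)
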