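import numpy as np
import pytest

from restbrain.volgrid import MaskVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.standard_normal((8, 8, 4)), spacing=(3.75, 3.75, 4.0))


@pytest.fixture
def full_mask():
    def _make(shape, spacing=(1.0, 1.0, 1.0)):
        return MaskVolume(np.ones(shape, dtype=np.uint8), spacing)
    return _make
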