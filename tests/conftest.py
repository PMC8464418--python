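import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_complex_image(rng):
    def _make(shape=(16, 16)):
        return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)

    return _make
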