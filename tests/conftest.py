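import numpy as np
import pytest

from ramanotype.simulate import NOISELESS, NoiseConfig, default_axis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def axis():
    return default_axis()


@pytest.fixture
def noiseless():
    return NOISELESS


@pytest.fixture
def default_noise():
    return NoiseConfig()
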