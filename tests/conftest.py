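import numpy as np
import pytest

from bispecg import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_signal(rng):
    """8 one-second segments of unit white noise at 128 Hz."""
    return Signal(rng.standard_normal(8 * 128), 128.0)
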