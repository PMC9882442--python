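import numpy as np
import pytest

from t2relax.signal_model import default_grid


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
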