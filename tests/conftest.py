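import numpy as np
import pytest

from latchnet import ModelParams


@pytest.fixture
def params():
    """Published operating point (12x12 network)."""
    return ModelParams()


@pytest.fixture
def small_params():
    """A small, fast network with short schedule for dynamics tests."""
    return ModelParams(H=4, M=4, item_clamp_s=0.2, isi_s=0.2,
                       recall_s=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
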