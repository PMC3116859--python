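import numpy as np
import pytest

from metarep import Params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """Small, fast default parameter set (b = g = 1, k in [2, 4])."""
    return Params(L=20, b=1.0, g=1.0, E_max=10.0, k_min=2.0, k_max=4.0, seed=7)
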