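import numpy as np
import pytest

from inrfqa.core import INRFParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return INRFParams()


@pytest.fixture
def small_params():
    """Cheap parameter set for tests where kernel size is irrelevant."""
    return INRFParams(sigma_m=1.0, sigma_w=3.0, sigma_g=1.0, lam=2.0)


@pytest.fixture
def random_image(rng):
    return rng.random((24, 24))
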