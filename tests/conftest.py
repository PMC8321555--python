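import numpy as np
import pytest

from mocsim.stp import DepressionParams, FacilitationParams


@pytest.fixture
def dep_params():
    return DepressionParams()


@pytest.fixture
def fac_params():
    return FacilitationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
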