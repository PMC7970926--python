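import numpy as np
import pytest

from thermoter import GibbsParams, LQParams, TERParams


@pytest.fixture
def cho_params() -> TERParams:
    """Published CHO-cell TER parameters (in-vitro clonogenic data)."""
    return TERParams(o=0.97, a_prime=1.00, b=0.95, Tg=48.07)


@pytest.fixture
def lq_default() -> LQParams:
    return LQParams(alpha=0.3, beta=0.03)


@pytest.fixture
def gibbs_default() -> GibbsParams:
    return GibbsParams(A=50.0e-21, B=3.0e-22, Tg=321.15)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
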