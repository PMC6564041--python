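import numpy as np
import pytest
from hypothesis import settings

from polyevo.interfaces import ModelParams

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Default model parameters (L_I=64, S_c=43/64, T=25)."""
    return ModelParams()


@pytest.fixture
def small_params():
    """Desk-scale parameters for exhaustive checks."""
    return ModelParams(L_I=8, S_c=0.75, T=25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ref_system():
    from polyevo.reference import reference_system

    return reference_system()
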