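import numpy as np
import pytest

from scopesight.phantom import PhantomSpec, generate_phantom
from scopesight.tracker import default_rig
from scopesight.tre import default_scope_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def scope_model(phantom):
    return default_scope_model(T_AT=phantom.T_AT)


@pytest.fixture(scope="session")
def rig():
    return default_rig()
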