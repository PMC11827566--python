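import numpy as np
import pytest

from twostep.task import TaskConfig
from twostep.variants import ParameterSet


@pytest.fixture(scope="session")
def mag_config():
    return TaskConfig("magnitude")


@pytest.fixture(scope="session")
def prob_config():
    return TaskConfig("probability")


@pytest.fixture
def hop_params():
    """A representative Q+HOP parameter set."""
    return ParameterSet(alpha1=0.3, alpha2=0.6, alpha3=0.95, alpha_hop=0.5,
                        beta_mb=6.0, beta_mf=1.5, beta_persev=1.5, beta2=6.0)


@pytest.fixture
def fop_params():
    return ParameterSet(alpha1=0.3, alpha2=0.6, alpha3=0.95,
                        beta_mb=6.0, beta_mf=1.5, beta_persev=1.5, beta2=6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
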