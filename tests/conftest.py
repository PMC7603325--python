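import numpy as np
import pytest

from aioa.experiments import gull_training_table
from aioa.features import default_acc_catalogue
from aioa.synthetic import make_gull_series


@pytest.fixture(scope="session")
def catalogue():
    return default_acc_catalogue()


@pytest.fixture(scope="session")
def gull_series():
    """A 15-min labelled synthetic gull trace shared across tests."""
    return make_gull_series(900.0, seed=42)


@pytest.fixture(scope="session")
def gull_table(gull_series, catalogue):
    X, y = gull_training_table(gull_series, catalogue)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
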