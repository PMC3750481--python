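import numpy as np
import pytest

from brdusim import Efficacy, Grid, RateModel, TimePartition


@pytest.fixture(scope="session")
def default_grid():
    return Grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20130812)


@pytest.fixture(scope="session")
def one_phase_10d():
    return TimePartition((0.0, 10.0))


@pytest.fixture(scope="session")
def equal_rates():
    return RateModel.constant(0.1, 0.1)


@pytest.fixture(scope="session")
def noisy_efficacies():
    """Normal uplabeling efficacy followed by pure dilution."""
    return (Efficacy.normal(1.0, 0.2), Efficacy.dirac(0.0))
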