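import pytest

from netenergy.model import FactorialNEModel
from netenergy.reference import reference_trial
from netenergy.simulate import SimParams, simulate_trial


@pytest.fixture(scope="session")
def ref_trial():
    """The bundled published-group-mean trial."""
    return reference_trial()


@pytest.fixture(scope="session")
def sim_linear():
    """Zero-noise trial under the linear RE-MEI generative law."""
    return simulate_trial(SimParams(hp_model="linear_re", seed=11))


@pytest.fixture(scope="session")
def sim_exp():
    """Zero-noise trial under the exponential heat-production law."""
    return simulate_trial(SimParams(hp_model="exponential", seed=11))


@pytest.fixture(scope="session")
def sim_noisy():
    """Trial with 2% multiplicative assay noise."""
    return simulate_trial(SimParams(noise_cv=0.02, seed=5))


@pytest.fixture(scope="session")
def fit_linear(sim_linear):
    return FactorialNEModel(sim_linear).fit()


@pytest.fixture(scope="session")
def fit_noisy(sim_noisy):
    return FactorialNEModel(sim_noisy).fit()
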