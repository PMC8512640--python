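import numpy as np
import pytest
from hypothesis import settings

from rbsarmax.model import Gamma

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from rbsarmax.simulate import SimScenario, simulate_rbsarmax


@pytest.fixture(scope="session")
def case1_gamma():
    """The central RBSARMAX(1,1,1) study parameters."""
    return Gamma(delta=8.0, eta=1.0, beta=[0.7], phi=[0.7], theta=[0.5])


@pytest.fixture(scope="session")
def mild_gamma():
    """A tamer RBSARMAX(1,1,1) setting with rare infeasible paths."""
    return Gamma(delta=8.0, eta=1.0, beta=[0.7], phi=[0.3], theta=[0.3])


def simulate_feasible(gamma, n, seed, max_tries=50):
    """Draw a series, skipping seeds whose path hits mu_t <= 0."""
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_tries):
        try:
            return simulate_rbsarmax(
                SimScenario(gamma=gamma, n=n, seed=child, regressor_seed=seed)
            )
        except RuntimeError:
            continue
    raise RuntimeError("no feasible path found")


@pytest.fixture(scope="session")
def fitted_111(mild_gamma):
    """One simulated-and-fitted RBSARMAX(1,1,1) dataset, n=500."""
    from rbsarmax.model import RBSARMAX

    data = simulate_feasible(mild_gamma, 500, seed=2024)
    res = RBSARMAX(data, order=(1, 1)).fit()
    assert res.converged
    return data, res
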