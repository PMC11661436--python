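import numpy as np
import pytest

import etsim


@pytest.fixture(scope="session")
def crossover():
    return etsim.get_preset("crossover-dynamics")


@pytest.fixture(scope="session")
def nonadiabatic():
    return etsim.get_preset("nonadiabatic-a")


@pytest.fixture(scope="session")
def crossover_trajectory(crossover):
    """One moderately long dissipative trajectory, shared across tests."""
    p = crossover
    return etsim.simulate_trajectory(
        p.model, p.bath, p.noise, p.init, tsim=250.0, n_samples=200
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
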