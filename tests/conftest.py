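import numpy as np
import pytest

import clicksim as cs


@pytest.fixture(scope="session")
def canonical():
    return cs.build_canonical_4click()


@pytest.fixture(scope="session")
def resting_trajectory(canonical):
    """The shipped resting-state run (help level 0, long horizon)."""
    return cs.simulate_ode(canonical, cs.OdeParams(t_end=2500.0, n_samples=2501))


@pytest.fixture(scope="session")
def resting_equilibrium(canonical, resting_trajectory):
    eq, stable = cs.find_equilibrium(canonical, resting_trajectory.final_state)
    return eq, stable


def single_logistic(r=1.0, d=0.0, K=1.0, init=0.01):
    """One-population logistic assembly used across tests."""
    pop = cs.Population(id="P", lineage="solo", stage=cs.Stage.YOUNG,
                        growth_rate=r, death_rate=d, initial_abundance=init)
    return cs.Assembly(populations=(pop,), carrying_capacity=K)
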