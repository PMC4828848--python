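import numpy as np
import pytest

import mmrmsim as m


@pytest.fixture(scope="session")
def design():
    return m.TrialDesign()


@pytest.fixture(scope="session")
def linear_means():
    return m.make_linear_trajectory(50.0, 4.18, 4)


@pytest.fixture(scope="session")
def complete_trial(design, linear_means):
    """One complete default trial at rho = 0.5."""
    variance = m.variance_components(110.0, 0.5)
    return m.simulate_trial(design, linear_means, variance, seed=20260920)


@pytest.fixture(scope="session")
def mcar_trial(complete_trial):
    return m.apply_mcar(complete_trial, m.SCENARIOS["mcar_equal"], seed=5)


def make_trial(n_per_arm=100, rho=0.5, seed=0, n_times=4, effect=4.18):
    design = m.TrialDesign(n_per_arm=n_per_arm, n_times=n_times)
    means = m.make_linear_trajectory(50.0, effect, n_times)
    variance = m.variance_components(110.0, rho)
    return m.simulate_trial(design, means, variance, seed)
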