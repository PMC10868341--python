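import numpy as np
import pytest

from deepcentroid import RunConfig, SimScenario, fit_cascade, simulate


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down study kept fast enough for unit tests."""
    return SimScenario(n_samples=80, n_features=300, n_informative=20, seed=3)


@pytest.fixture(scope="session")
def small_sim(small_scenario):
    return simulate(small_scenario)


@pytest.fixture(scope="session")
def fast_config():
    """Small ensemble for unit tests; defaults are exercised elsewhere."""
    return RunConfig(n_feature_sets=60, set_size_min=5, set_size_max=30, max_layers=5, seed=7)


@pytest.fixture(scope="session")
def fitted_model(small_sim, fast_config):
    return fit_cascade(small_sim.train_X, small_sim.train_y, fast_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
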