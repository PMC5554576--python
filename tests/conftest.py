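import numpy as np
import pytest

import bayescox as bc


@pytest.fixture(scope="session")
def tiny_survival():
    """Ten subjects, a handful of tied event times, two covariates."""
    rng = np.random.default_rng(7)
    times = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0, 5.0, 6.0])
    status = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 1])
    X = rng.standard_normal((10, 2))
    return times, status, X


@pytest.fixture(scope="session")
def sparse_scenario():
    return bc.make_scenario("sparse", seed=1)


@pytest.fixture(scope="session")
def sparse_data(sparse_scenario):
    X, t, d = bc.simulate_dataset(sparse_scenario)
    return X, t, d
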