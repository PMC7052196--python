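import numpy as np
import pytest

import arrbfn as ar


@pytest.fixture(scope="session")
def logistic_ts() -> ar.TimeSeriesSet:
    """Noise-free 3000-step ring-coupled logistic trajectory."""
    return ar.simulate_coupled_logistic(initial_state=(0.41, 0.53, 0.47))


@pytest.fixture(scope="session")
def partition(logistic_ts) -> ar.DatasetPartition:
    return ar.make_partition(logistic_ts)


@pytest.fixture(scope="session")
def noisy_ts(logistic_ts) -> ar.TimeSeriesSet:
    """The same trajectory with 10% observational noise."""
    return ar.add_observational_noise(logistic_ts, ar.NoiseSpec(level=0.10, seed=202))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
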