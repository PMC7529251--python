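import numpy as np
import pytest

from censnet import CNEConfig, SimConfig, generate_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """J=5, N=200 scale-free dataset with ~60% censoring."""
    return generate_data(SimConfig(n_samples=200, n_events=5, lam=1.0, seed=11))


@pytest.fixture(scope="session")
def uncensored_dataset():
    """J=5, N=200 dataset with negligible censoring (tiny exponential rate)."""
    return generate_data(SimConfig(n_samples=200, n_events=5, lam=1e-6, seed=13))


@pytest.fixture
def config():
    return CNEConfig()
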