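import numpy as np
import pytest

from appleseg import PhantomConfig, generate_samples


@pytest.fixture(scope="session")
def phantom_pair():
    """Small in-memory phantom set shared across tests: (healthy, defective)."""
    cfg = PhantomConfig(n_healthy=4, n_defective=4, seed=7)
    return generate_samples(cfg)


@pytest.fixture(scope="session")
def healthy_samples(phantom_pair):
    return phantom_pair[0]


@pytest.fixture(scope="session")
def defective_samples(phantom_pair):
    return phantom_pair[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
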