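import numpy as np
import pytest

from sms import SimConfig, compute_features, simulate_deployment


@pytest.fixture(scope="session")
def mixed_dep():
    """A 2 h deployment with the default behaviour budget, shared by tests
    that only read from it."""
    return simulate_deployment(SimConfig(duration_s=7200, seed=9))


@pytest.fixture(scope="session")
def mixed_features(mixed_dep):
    return compute_features(mixed_dep.stream)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
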