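import numpy as np
import pytest

from obsinfer.io import make_fixtures
from obsinfer.stimuli import generate_stimulus, sample_markov_model


@pytest.fixture(scope="session")
def bundle():
    """Deterministic order-2 fixture bundle with slow-path reference logliks."""
    return make_fixtures(seed=2024, length=300, r_max=4)


@pytest.fixture(scope="session")
def order1_stimulus():
    """A clearly structured order-1 stimulus of 300 trials."""
    model = sample_markov_model(1, concentration=1.0, seed=5, min_order_gap=0.1)
    return generate_stimulus(model, 300, seed=6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
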