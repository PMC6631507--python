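import numpy as np
import pytest

from armband_bench.evaluation_stats import generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Three-participant default-difficulty study shared across tests."""
    return generate_study(n_participants=3, seed=7)
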