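import numpy as np
import pytest

from respyro import TimeGrid, build_operator, make_test_problem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return TimeGrid(n=64, dt=0.5)


@pytest.fixture(scope="session")
def default_problem():
    """The standard simulated study: n = 512, 0.5% noise."""
    return make_test_problem(n=512, level=0.005, seed=1)


@pytest.fixture
def random_operator(rng):
    """A 64-dim causal Toeplitz operator with a random kernel."""
    return build_operator(rng.standard_normal(64))
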