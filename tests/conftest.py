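import numpy as np
import pytest

from dynthresh.beliefs import BeliefGrid, GaussianEvidenceModel
from dynthresh.contexts import make_reward_change_schedule, make_static_schedule


@pytest.fixture(scope="session")
def grid():
    return BeliefGrid()


@pytest.fixture(scope="session")
def small_grid():
    return BeliefGrid(n_points=101)


@pytest.fixture(scope="session")
def model():
    """Reference evidence model: quality m = 5 at unit noise, 10 ms steps."""
    return GaussianEvidenceModel(mu=np.sqrt(2.5), sigma=1.0, delta_t=0.01)


@pytest.fixture(scope="session")
def static_context():
    return make_static_schedule()


@pytest.fixture(scope="session")
def low_to_high_context():
    return make_reward_change_schedule(3.0, 8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
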