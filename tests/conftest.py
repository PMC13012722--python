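import numpy as np
import pytest

from socdec import agents


@pytest.fixture(scope="session")
def small_cohort():
    """Six agents, two sessions, responsibility-redux truth."""
    return agents.simulate_cohort(n=6, sessions=2, seed=1)


@pytest.fixture(scope="session")
def redux_cohort():
    """Twenty agents, two sessions: large enough for sign checks on the
    social partner-RPE effect."""
    return agents.simulate_cohort(n=20, sessions=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
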