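import numpy as np
import pytest

from neurosync import FrequencyModel, simulate_condition


@pytest.fixture(scope="session")
def focused_traj():
    """One seeded focused-condition run shared across read-only tests."""
    return simulate_condition(FrequencyModel(), "focused", n=10, dt=0.01, duration=10.0, seed=0)


@pytest.fixture(scope="session")
def synced_alpha_traj():
    """Strongly coupled population with no common drive: a ~10 Hz collective rhythm."""
    return simulate_condition(FrequencyModel(), "resting", n=10, dt=0.01, duration=10.0, seed=0, K=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
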