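import numpy as np
import pytest

from fiberphot import (
    BehaviorSpec,
    SimParams,
    preprocess_session,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_session():
    """One simulated novel-day social session with ground truth."""
    params = SimParams()
    behavior = BehaviorSpec(paradigm="social_novel")
    return simulate_session(params, behavior, seed=7, animal_id="a00")


@pytest.fixture(scope="session")
def processed_session(default_session):
    trace, events, truth = default_session
    return preprocess_session(trace), events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
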