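import numpy as np
import pytest

from valuedyn import choice_model as cm
from valuedyn import task_synth as ts


@pytest.fixture(scope="session")
def small_session():
    """Two short runs (80 offers, 3 payouts) for design/BOLD tests."""
    return ts.make_session_design(80, 2, 3, seed=1)


@pytest.fixture(scope="session")
def mild_agent():
    """Weak-preference agent whose choices stay comfortably stochastic."""
    return ts.AgentSpec(beta0=0.5, beta_r=0.08, beta_s=-0.07)


@pytest.fixture(scope="session")
def small_estimates(small_session, mild_agent):
    """Trial estimates for the small session (fitted, not ground truth)."""
    trials = ts.simulate_behavior(mild_agent, small_session, seed=3)
    model = cm.fit_choice_model(trials)
    assert not model.separation_flag
    return cm.trial_estimates(model, trials)


@pytest.fixture(scope="session")
def paper_session():
    """The full session layout: 189 offers, six runs, ten payout trials."""
    return ts.make_session_design(189, 6, 10, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
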