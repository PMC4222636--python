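import numpy as np
import pytest

from dpkf.task import DEFAULT_AGENT, build_session, simulate_responses


@pytest.fixture(scope="session")
def agent_cohort():
    """20 synthetic DP-KF participants with full 12-block sessions."""
    rng = np.random.default_rng(20240601)
    sessions, responses = [], []
    for p in range(20):
        s = build_session(f"agent{p:02d}", rng)
        sessions.append(s)
        responses.append(simulate_responses(s, DEFAULT_AGENT, rng))
    return sessions, responses


@pytest.fixture(scope="session")
def kf_cohort():
    """20 single-mode (alpha = 0) agents on the same task."""
    hyper = DEFAULT_AGENT.replace(alpha=0.0, beta=0.0)
    rng = np.random.default_rng(20240602)
    sessions, responses = [], []
    for p in range(20):
        s = build_session(f"kfagent{p:02d}", rng)
        sessions.append(s)
        responses.append(simulate_responses(s, hyper, rng))
    return sessions, responses
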