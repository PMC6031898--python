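import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ccat import AgentParams, BatteryAgent, RunSeed, perfect_agent
from ccat.synthetic_agents import ResponderParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def seed():
    return RunSeed(42, "test")


@pytest.fixture
def agent():
    """Stochastic but fully seeded battery respondent."""
    return BatteryAgent(AgentParams())


@pytest.fixture
def perfect():
    """Deterministic always-correct respondent."""
    return perfect_agent()


@pytest.fixture
def sloppy():
    """Responder with level-graded accuracy, used for staircase tests."""
    return BatteryAgent(AgentParams(
        responder=ResponderParams(p_correct={1: 0.95, 2: 0.9, 3: 0.85},
                                  p_correct_default=0.5)))
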