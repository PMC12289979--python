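import pytest

from lossavoid.games import GameType, canonical_series
from lossavoid.choice_model import (
    LOSS_AVOIDANT_VF,
    ValueFunction,
    default_choice_model,
)
from lossavoid.synthetic_data import (
    AgentParams,
    simulate_iterated_group,
    simulate_one_shot,
)


@pytest.fixture(scope="session")
def cm():
    """Choice model calibrated on the all-gain PD base (delta0 = -1.5)."""
    return default_choice_model()


@pytest.fixture(scope="session")
def pd_series():
    return canonical_series(GameType.PD)


@pytest.fixture(scope="session")
def avoidant_agents():
    """Homogeneous loss-avoidant population (lambda=1, b=4)."""
    return AgentParams(vf=LOSS_AVOIDANT_VF)


@pytest.fixture(scope="session")
def null_agents():
    """Gain/loss-symmetric population (identity utility)."""
    return AgentParams(vf=ValueFunction(1.0, 0.0))


@pytest.fixture(scope="session")
def one_shot_pd(avoidant_agents):
    """One-shot PD sample at 120 per category under loss avoidance."""
    return simulate_one_shot(120, [GameType.PD], avoidant_agents, seed=2024)


@pytest.fixture(scope="session")
def iterated_pd(avoidant_agents):
    """Four iterated groups (12x5 design) with moderate reciprocity."""
    agents = AgentParams(vf=avoidant_agents.vf, w=0.5)
    return simulate_iterated_group(4, (12, 5), agents, seed=555)
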