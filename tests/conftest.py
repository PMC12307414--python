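import numpy as np
import pytest

from banditglx.models import AgentParameters
from banditglx.task import TaskConfig, make_block_schedule, simulate_agent


@pytest.fixture(scope="session")
def schedule80():
    return make_block_schedule(TaskConfig(n_trials=80), seed=11)


@pytest.fixture(scope="session")
def model4_dataset(schedule80):
    params = AgentParameters(epsilon=0.6, tau=0.8, decay=0.7)
    return simulate_agent(4, params, schedule80, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
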