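import numpy as np
import pytest

from infolearn import synth
from infolearn.behavior import QParams


@pytest.fixture(scope="session")
def behavior_session():
    """One simulated two-session subject with its PE table (seeded)."""
    table, pe = synth.generate_behavior(
        synth.TaskConfig(n_sessions=2), QParams(0.3, 0.2, 0.1), seed=42
    )
    return table, pe


@pytest.fixture(scope="session")
def pe_table(behavior_session):
    return behavior_session[1]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
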