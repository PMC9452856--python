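import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coreshell as cs

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return cs.table1()


@pytest.fixture(scope="session")
def table1_reference():
    return cs.table1("reference")


@pytest.fixture(scope="session")
def t24(table1):
    """Entrained fixed point at T = 24 h: (report, delta_psi, peak lead)."""
    report, dpsi, lead = cs.entrained_state(table1, 24.0)
    assert report.stable
    return report, dpsi, lead


@pytest.fixture(scope="session")
def dd_state(table1):
    """Synchronized free-running DD state."""
    state = cs.free_running_state(table1)
    assert state.stable
    return state


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220717)
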