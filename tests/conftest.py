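import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synpool as sp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_rates() -> sp.RateSet:
    return sp.DEFAULT_RATES


@pytest.fixture(scope="session")
def equilibrium(paper_rates) -> sp.PoolState:
    return sp.steady_state(paper_rates)


@pytest.fixture(scope="session")
def default_grid() -> np.ndarray:
    return np.arange(0.0, 1081.0, 1.0)


@pytest.fixture(scope="session")
def lpa_trajectory(equilibrium, default_grid) -> sp.Trajectory:
    """Full staged scenario: beta collapse at 240 s, alpha boost at 300 s."""
    return sp.simulate(sp.build_lpa_schedule(sp.ScenarioParams()), equilibrium, default_grid)


@pytest.fixture(scope="session")
def alpha_only_trajectory(equilibrium, default_grid) -> sp.Trajectory:
    """Control scenario: only the alpha boost at 300 s, beta untouched."""
    params = sp.ScenarioParams(lead=0.0, beta_change_value=1.0)
    return sp.simulate(sp.build_lpa_schedule(params), equilibrium, default_grid)
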