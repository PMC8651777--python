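import numpy as np
import pytest

from airshift import SimulationConfig, run_state, simulate_state_series


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    """Desk-scale generating process: 12-week cycle, 5 cycles of history."""
    return SimulationConfig(delta_true=5.0, master_seed=7)


@pytest.fixture(scope="session")
def desk_series(desk_config):
    series, truth = simulate_state_series(desk_config, "XX")
    return series, truth


@pytest.fixture(scope="session")
def desk_forecast(desk_series):
    """One completed bagged counterfactual, shared across read-only tests."""
    series, _ = desk_series
    return run_state(series, B=30, m=12, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
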