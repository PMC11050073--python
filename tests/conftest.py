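import pytest

import opiflow as of


@pytest.fixture(scope="session")
def cfg() -> of.ModelConfig:
    return of.default_config()


@pytest.fixture(scope="session")
def params(cfg) -> of.ParameterSet:
    """The calibrated parameter set (rho=0.000318, chi=0.1, psi=10)."""
    return cfg.parameter_set("optimized")


@pytest.fixture(scope="session")
def params_initial(cfg) -> of.ParameterSet:
    return cfg.parameter_set("initial")


@pytest.fixture(scope="session")
def schedules(cfg) -> of.ScheduleSet:
    return cfg.schedule_set()


@pytest.fixture(scope="session")
def initial_state(cfg) -> of.StockState:
    return cfg.initial_state()


@pytest.fixture(scope="session")
def baseline_48(initial_state, params, schedules) -> of.Trajectory:
    """The calibrated 2016-2019 baseline run, shared across tests."""
    return of.run(initial_state, params, schedules, 48)
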