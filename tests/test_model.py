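"""Flow computation and the one-month state update."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import opiflow as of
from opiflow.model import LIVING_STOCKS


def literal_flows(state, p, beta, upsilon, phi, tau):
    """Independent literal transcription of the 25 flow equations.

    Kept deliberately separate from the implementation (plain dict, scalar
    arithmetic, schedule values passed in directly) so it can serve as an
    oracle for compute_flows.
    """
    A = state.B + state.C + state.D + state.E + state.F + state.G + state.H + state.I
    return {
        "pop_increase": A * p.alpha,
        "start_short": state.B * beta * p.gamma,
        "stop_short": state.C * p.delta,
        "short_to_nap": state.C * p.epsilon / 10,
        "start_long": state.B * beta * (1.0 - p.gamma),
        "stop_long": state.D * p.zeta,
        "prev_long_to_long": state.E * p.eta * (1.0 - p.gamma),
        "prev_long_to_short": state.E * p.eta * p.gamma,
        "long_to_nap": state.D * p.epsilon,
        "prev_long_to_nouse": state.E * p.theta,
        "long_allcause_death": state.D * p.iota,
        "nap_to_nonmed": state.F * p.kappa,
        "stop_nap": state.F * p.mu * 2,
        "prev_nap_to_nouse": state.G * p.nu,
        "restart_nap": state.G * (p.xi / 2),
        "start_nonmed": state.B * p.lambda_,
        "stop_nonmed": state.H * p.mu,
        "restart_nonmed": state.I * p.xi,
        "prev_nonmed_to_nouse": state.I * p.nu,
        "nonmed_allcause_death": state.H * p.sigma,
        "long_od_death": state.D * p.omicron,
        "short_od_death": state.C * p.pi_,
        "nap_od_death": state.F * p.rho * p.chi * phi * tau,
        "nonmed_nonfent_od_death": state.H * p.rho * phi * tau,
        "nonmed_fent_od_death": state.H * p.rho * p.psi * upsilon * phi * tau,
    }


def _random_setup(rng):
    """A random small state, parameter draw, and single-year schedule."""
    stocks = rng.uniform(0, 1e6, 8)
    month = int(rng.integers(0, 12))
    state = of.StockState(month, *stocks)
    base = {f.name: rng.uniform(0.0, 0.05) for f in dataclasses.fields(of.ParameterSet)}
    base.update(gamma=rng.uniform(0, 1), chi=rng.uniform(0.05, 5), psi=rng.uniform(1, 20))
    params = of.ParameterSet(**base)
    beta = rng.uniform(0.001, 0.01)
    upsilon = rng.uniform(0.1, 2.0)
    prevented = rng.uniform(0, 1)
    schedules = of.ScheduleSet(
        beta_by_year={2016: beta},
        upsilon_by_year={2016: upsilon},
        tau_by_quarter={1: 1.02, 2: 1.01, 3: 0.95, 4: 0.99},
        prevented_overrides={month: prevented},
    )
    return state, params, schedules, beta, upsilon, 1.0 - prevented


def test_zero_state_gives_zero_flows(params, schedules):
    state = of.StockState(0, *([0.0] * 8))
    flows = of.compute_flows(state, params, schedules)
    assert all(getattr(flows, f.name) == 0.0 for f in dataclasses.fields(flows))


def test_flows_at_published_initial_state(initial_state, params, schedules):
    """January 2016, calibrated parameters: spot-check two flows by hand arithmetic."""
    flows = of.compute_flows(initial_state, params, schedules)
    # long-term overdose deaths: 690,594 * 0.0000582769
    assert flows.long_od_death == pytest.approx(690_594 * 0.0000582769)
    assert flows.long_od_death == pytest.approx(40.24, abs=0.01)
    # fentanyl deaths: 200,000 * 0.000318 * 10 * upsilon(2016)=0.25 * phi=1 * tau(Q1)=1.02
    assert flows.nonmed_fent_od_death == pytest.approx(162.18, abs=0.01)
    assert flows.overdose_deaths == pytest.approx(
        flows.long_od_death + flows.short_od_death + flows.nap_od_death
        + flows.nonmed_nonfent_od_death + flows.nonmed_fent_od_death
    )


def test_full_prevention_annihilates_only_intervention_bearing_flows(
    initial_state, params, schedules
):
    full = dataclasses.replace(schedules, prevented_overrides={0: 1.0})
    f0 = of.compute_flows(initial_state, params, schedules)
    f1 = of.compute_flows(initial_state, params, full)
    assert f1.nap_od_death == 0.0
    assert f1.nonmed_nonfent_od_death == 0.0
    assert f1.nonmed_fent_od_death == 0.0
    assert f1.long_od_death == f0.long_od_death
    assert f1.short_od_death == f0.short_od_death


def test_flows_match_literal_transcription_oracle():
    rng = np.random.default_rng(20160101)
    for _ in range(5):
        state, params, schedules, beta, upsilon, phi = _random_setup(rng)
        flows = of.compute_flows(state, params, schedules)
        expected = literal_flows(state, params, beta, upsilon, phi,
                                 schedules.tau(state.month_index))
        for name, value in expected.items():
            assert getattr(flows, name) == value, name


def test_negative_stock_rejected(params, schedules):
    state = of.StockState(0, B=1.0, C=-5.0, D=0, E=0, F=0, G=0, H=0, I=0)
    with pytest.raises(of.StateError, match="C"):
        of.compute_flows(state, params, schedules)


def test_month_outside_schedule_coverage(initial_state, params, schedules):
    far = dataclasses.replace(initial_state, month_index=1200)
    with pytest.raises(of.ScheduleRangeError):
        of.compute_flows(far, params, schedules)


def test_step_identity_on_zero_flows(initial_state):
    zero = of.FlowSet(*([0.0] * 25))
    nxt = of.step(initial_state, zero)
    assert nxt.month_index == initial_state.month_index + 1
    for name in LIVING_STOCKS + ("J", "K", "L"):
        assert getattr(nxt, name) == getattr(initial_state, name)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    stocks=st.lists(st.floats(0, 1e7, allow_nan=False), min_size=8, max_size=8),
    draw=st.integers(0, 2**31 - 1),
)
def test_step_conserves_people(stocks, draw):
    """Change in living population = inflow minus the five death flows."""
    rng = np.random.default_rng(draw)
    state = of.StockState(0, *stocks)
    # small random rates keep every stock's outflow fraction below 1
    fracs = {s: rng.uniform(0, 0.05, 4) for s in LIVING_STOCKS}
    values = {f.name: 0.0 for f in dataclasses.fields(of.FlowSet)}
    values.update(
        pop_increase=rng.uniform(0, 1e4),
        start_short=state.B * fracs["B"][0], start_long=state.B * fracs["B"][1],
        start_nonmed=state.B * fracs["B"][2],
        stop_short=state.C * fracs["C"][0], short_to_nap=state.C * fracs["C"][1],
        short_od_death=state.C * fracs["C"][2],
        stop_long=state.D * fracs["D"][0], long_to_nap=state.D * fracs["D"][1],
        long_allcause_death=state.D * fracs["D"][2], long_od_death=state.D * fracs["D"][3],
        prev_long_to_long=state.E * fracs["E"][0], prev_long_to_short=state.E * fracs["E"][1],
        prev_long_to_nouse=state.E * fracs["E"][2],
        nap_to_nonmed=state.F * fracs["F"][0], stop_nap=state.F * fracs["F"][1],
        nap_od_death=state.F * fracs["F"][2],
        prev_nap_to_nouse=state.G * fracs["G"][0], restart_nap=state.G * fracs["G"][1],
        stop_nonmed=state.H * fracs["H"][0], nonmed_allcause_death=state.H * fracs["H"][1],
        nonmed_nonfent_od_death=state.H * fracs["H"][2],
        nonmed_fent_od_death=state.H * fracs["H"][3],
        restart_nonmed=state.I * fracs["I"][0], prev_nonmed_to_nouse=state.I * fracs["I"][1],
    )
    flows = of.FlowSet(**values)
    nxt = of.step(state, flows)
    expected_change = flows.pop_increase - flows.total_deaths
    assert math.isclose(nxt.A - state.A, expected_change, rel_tol=1e-9, abs_tol=1e-6)
    assert nxt.K - state.K == pytest.approx(flows.overdose_deaths)


def test_long_run_stays_non_negative_without_clipping(
    initial_state, params, schedules, caplog
):
    """120-month run from the published initial stocks: no negative stocks,
    no clipping, and non-decreasing cumulative death sinks."""
    extended = of.extend_fentanyl(schedules, "same", 2025)
    with caplog.at_level("WARNING", logger="opiflow.model"):
        traj = of.run(initial_state, params, extended, 120)
    assert not caplog.records, "negative-stock clipping should never fire"
    prev = traj.states[0]
    for state in traj.states[1:]:
        state.validate()
        assert state.J >= prev.J and state.K >= prev.K and state.L >= prev.L
        prev = state
    assert all(
        getattr(f, fld.name) >= 0
        for f in traj.flows
        for fld in dataclasses.fields(of.FlowSet)
    )


@pytest.mark.parametrize("field,factor", [("psi", 1.5), ("rho", 1.5)])
def test_cumulative_deaths_increase_with_mortality_parameters(
    initial_state, params, schedules, field, factor
):
    base = of.run(initial_state, params, schedules, 48).cumulative_od_deaths
    bumped = dataclasses.replace(params, **{field: getattr(params, field) * factor})
    assert of.run(initial_state, bumped, schedules, 48).cumulative_od_deaths >= base


def test_cumulative_deaths_increase_with_fentanyl_and_lower_prevention(
    initial_state, params, schedules
):
    base = of.run(initial_state, params, schedules, 48).cumulative_od_deaths
    more_fent = dataclasses.replace(
        schedules,
        upsilon_by_year={y: 1.2 * v for y, v in schedules.upsilon_by_year.items()},
    )
    assert of.run(initial_state, params, more_fent, 48).cumulative_od_deaths >= base
    weaker_ramp = dataclasses.replace(
        schedules, prevented_ramp=of.PreventedRamp(end_value=0.40)
    )
    assert of.run(initial_state, params, weaker_ramp, 48).cumulative_od_deaths >= base
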