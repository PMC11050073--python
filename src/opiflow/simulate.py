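"""Running the model over a horizon, quarterly aggregation, scenarios.

The simulator iterates the monthly flow computation and state update from a
starting state. Overdose deaths are aggregated to calendar quarters for
comparison with national surveillance, which is released quarterly. Two
study designs sit on top of the plain run: a zero-intervention
counterfactual over the pre-pandemic period, and four COVID-era scenarios
crossing held-vs-higher intervention effect with held-vs-trend fentanyl
penetration (labelled HI1F1, HI1F2, HI2F1, HI2F2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import FlowSet, ParameterSet, StockState, compute_flows, step
from .schedules import ScheduleSet, extend_fentanyl, extend_prevention, zero_prevention


@dataclass
class Trajectory:
    """Monthly history of a run: ``months + 1`` states and ``months`` flow sets."""

    states: list[StockState]
    flows: list[FlowSet]
    start_year: int = 2016

    def __post_init__(self):
        if len(self.states) != len(self.flows) + 1:
            raise ConfigError("trajectory needs exactly one more state than flow sets")

    @property
    def months(self) -> int:
        return len(self.flows)

    @property
    def monthly_od_deaths(self) -> np.ndarray:
        """Opioid overdose deaths per simulated month (flows u+v+w+x+y)."""
        return np.array([f.overdose_deaths for f in self.flows])

    @property
    def cumulative_od_deaths(self) -> float:
        return float(self.monthly_od_deaths.sum())

    def period_of(self, month_index: int) -> pd.Period:
        return pd.Period(
            year=self.start_year + month_index // 12,
            quarter=(month_index % 12) // 3 + 1,
            freq="Q",
        )


def run(
    initial: StockState,
    params: ParameterSet,
    schedules: ScheduleSet,
    months: int,
) -> Trajectory:
    """Simulate ``months`` monthly steps from ``initial``. Deterministic."""
    states = [initial]
    flows: list[FlowSet] = []
    state = initial
    for _ in range(months):
        f = compute_flows(state, params, schedules)
        state = step(state, f)
        flows.append(f)
        states.append(state)
    return Trajectory(states=states, flows=flows, start_year=schedules.start_year)


def quarterly_deaths(traj: Trajectory) -> pd.Series:
    """Aggregate monthly overdose deaths into calendar quarters.

    The trajectory must start at a quarter boundary; a partial trailing
    quarter is dropped with a warning. Returns a Series named ``deaths``
    with a quarterly PeriodIndex (e.g. ``2016Q1``).
    """
    m0 = traj.states[0].month_index
    if m0 % 3 != 0:
        raise ConfigError(f"trajectory starts mid-quarter (month_index={m0})")
    n_quarters, remainder = divmod(traj.months, 3)
    if remainder:
        warnings.warn(
            f"dropping {remainder} trailing month(s) that do not fill a quarter",
            stacklevel=2,
        )
    monthly = traj.monthly_od_deaths[: n_quarters * 3]
    values = monthly.reshape(n_quarters, 3).sum(axis=1)
    index = pd.period_range(traj.period_of(m0), periods=n_quarters, freq="Q")
    return pd.Series(values, index=index, name="deaths")


def run_counterfactual(
    params: ParameterSet,
    schedules: ScheduleSet,
    months: int = 48,
    initial: StockState | None = None,
) -> Trajectory:
    """Re-run the pre-pandemic period with the intervention effect removed.

    Identical to :func:`run` except that the prevented proportion is forced
    to zero throughout (survival multiplier phi = 1), quantifying deaths
    that would have occurred absent the post-2016 interventions under the
    model's assumptions.
    """
    if initial is None:
        initial = StockState.initial()
    return run(initial, params, zero_prevention(schedules), months)


@dataclass(frozen=True)
class ScenarioSpec:
    """One COVID-era scenario: how prevention and fentanyl evolve past the data."""

    prevention_mode: str  # 'same' | 'higher'
    fentanyl_mode: str    # 'same' | 'trend'
    horizon_months: int = 15

    def __post_init__(self):
        if self.horizon_months < 1:
            raise ConfigError("scenario horizon must be at least 1 month")
        if self.prevention_mode not in ("same", "higher"):
            raise ConfigError(f"unknown prevention mode: {self.prevention_mode!r}")
        if self.fentanyl_mode not in ("same", "trend"):
            raise ConfigError(f"unknown fentanyl mode: {self.fentanyl_mode!r}")

    @property
    def name(self) -> str:
        hi = 1 if self.prevention_mode == "same" else 2
        f = 1 if self.fentanyl_mode == "same" else 2
        return f"HI{hi}F{f}"


#: The four scenarios crossed in the COVID-era analysis.
DEFAULT_SCENARIOS = (
    ScenarioSpec("same", "same"),
    ScenarioSpec("same", "trend"),
    ScenarioSpec("higher", "same"),
    ScenarioSpec("higher", "trend"),
)


def run_scenarios(
    params: ParameterSet,
    schedules: ScheduleSet,
    specs: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS,
    start_month: int = 69,
    prevention_increment: float = 0.10,
    initial: StockState | None = None,
) -> dict[str, pd.Series]:
    """Simulate each scenario from the baseline state at ``start_month``.

    The baseline is first run from ``initial`` (default: the January 2016
    stocks) up to ``start_month``, which must be a quarter boundary — the
    default 69 is October 2021, matching a five-quarter projection through
    December 2022. Each scenario extends the fentanyl proxy (hold or OLS
    trend) and the prevented proportion (hold or +``prevention_increment``,
    capped at 1) over its horizon, then simulates forward. Returns quarterly
    death series keyed by scenario name.
    """
    if start_month % 3 != 0:
        raise ConfigError(f"scenario start month {start_month} is not a quarter boundary")
    if initial is None:
        initial = StockState.initial()
    baseline = run(initial, params, schedules, start_month)
    start_state = baseline.states[-1]

    results: dict[str, pd.Series] = {}
    for spec in specs:
        end_year = schedules.start_year + (start_month + spec.horizon_months - 1) // 12
        sched = extend_fentanyl(schedules, spec.fentanyl_mode, end_year)
        sched = extend_prevention(
            sched,
            spec.prevention_mode,
            months=spec.horizon_months,
            increment=prevention_increment,
            start_month=start_month,
        )
        traj = run(start_state, params, sched, spec.horizon_months)
        results[spec.name] = quarterly_deaths(traj)
    return results
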