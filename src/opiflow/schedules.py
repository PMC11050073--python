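"""Time-varying model inputs: beta, upsilon, phi and tau.

Four inputs vary over time:

* ``beta`` — per-month opioid prescription-initiation rate, piecewise
  constant by calendar year (declining 2016-2019 as prescribing tightened);
* ``upsilon`` — a dimensionless proxy for fentanyl penetration of the
  unregulated drug supply, indexed to 2020 = 1.00, also annual;
* ``prevented`` — the proportion of overdose deaths averted by health
  interventions rolled out since January 2016 (naloxone distribution,
  opioid agonist therapy, supervised consumption, Good Samaritan law),
  ramping linearly from 0 at month 0 to 0.60 at month 47 and held
  thereafter; it enters the mortality flows as the survival multiplier
  ``phi = 1 - prevented``;
* ``tau`` — a quarterly seasonality multiplier on overdose mortality.

Scenario analysis extends ``upsilon`` beyond the observed years (hold or
linear trend) and ``prevented`` beyond the ramp (hold or step up).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ScheduleRangeError

#: Annual prescription-initiation rates (per year; divide by 12 for monthly).
#: Published values cover the first four years; later years hold the 2019
#: value, consistent with the plateau in opioid prescribing after 2019.
DEFAULT_BETA_ANNUAL = {
    2016: 0.0866, 2017: 0.0838, 2018: 0.0810, 2019: 0.0782,
    2020: 0.0782, 2021: 0.0782,
}

#: Fentanyl-penetration proxy by year, 2020 = 1.00. The 2019 entry is 0.80,
#: consistent with the otherwise monotone 2016-2021 trend; see docs/methods.md.
DEFAULT_UPSILON = {2016: 0.25, 2017: 0.48, 2018: 0.61, 2019: 0.80, 2020: 1.00, 2021: 1.22}

#: Seasonality multiplier by calendar quarter.
DEFAULT_TAU = {1: 1.02, 2: 1.01, 3: 0.95, 4: 0.99}


@dataclass(frozen=True)
class PreventedRamp:
    """Linear ramp of the prevented proportion, held constant after the end."""

    start_month: int = 0
    end_month: int = 47
    end_value: float = 0.60

    def value(self, month_index: int) -> float:
        if month_index <= self.start_month:
            return 0.0
        if month_index >= self.end_month:
            return self.end_value
        frac = (month_index - self.start_month) / (self.end_month - self.start_month)
        return self.end_value * frac


@dataclass(frozen=True)
class ScheduleSet:
    """The four time-varying inputs, anchored to ``start_year`` (month 0 = January)."""

    beta_by_year: dict[int, float]      # monthly rates
    upsilon_by_year: dict[int, float]
    tau_by_quarter: dict[int, float]
    prevented_ramp: PreventedRamp = field(default_factory=PreventedRamp)
    prevented_overrides: dict[int, float] = field(default_factory=dict)
    start_year: int = 2016

    def __post_init__(self):
        if sorted(self.tau_by_quarter) != [1, 2, 3, 4]:
            raise ConfigError("tau_by_quarter must have exactly quarters 1-4")
        if any(v <= 0 for v in self.tau_by_quarter.values()):
            raise ConfigError("tau values must be positive")
        if any(v <= 0 for v in self.upsilon_by_year.values()):
            raise ConfigError("upsilon values must be positive")
        bad = {m: v for m, v in self.prevented_overrides.items() if not 0 <= v <= 1}
        if bad or not 0 <= self.prevented_ramp.end_value <= 1:
            raise ConfigError("prevented proportions must lie in [0, 1]")

    # -- calendar helpers ---------------------------------------------------
    def year_of(self, month_index: int) -> int:
        return self.start_year + month_index // 12

    def quarter_of(self, month_index: int) -> int:
        return (month_index % 12) // 3 + 1

    # -- lookups ------------------------------------------------------------
    def beta(self, month_index: int) -> float:
        year = self.year_of(month_index)
        try:
            return self.beta_by_year[year]
        except KeyError:
            raise ScheduleRangeError(f"beta not defined for year {year}") from None

    def upsilon(self, month_index: int) -> float:
        year = self.year_of(month_index)
        try:
            return self.upsilon_by_year[year]
        except KeyError:
            raise ScheduleRangeError(f"upsilon not defined for year {year}") from None

    def tau(self, month_index: int) -> float:
        return self.tau_by_quarter[self.quarter_of(month_index)]

    def prevented(self, month_index: int) -> float:
        """Proportion of overdose deaths prevented by interventions this month."""
        if month_index in self.prevented_overrides:
            return self.prevented_overrides[month_index]
        return self.prevented_ramp.value(month_index)

    def phi_multiplier(self, month_index: int) -> float:
        """Survival multiplier on overdose mortality: 1 - prevented."""
        return 1.0 - self.prevented(month_index)

    def last_upsilon_year(self) -> int:
        return max(self.upsilon_by_year)


def build_default_schedules(
    beta_annual: dict[int, float] | None = None,
    upsilon_by_year: dict[int, float] | None = None,
    tau_by_quarter: dict[int, float] | None = None,
    prevented_ramp: PreventedRamp | None = None,
    prevented_overrides: dict[int, float] | None = None,
    start_year: int = 2016,
) -> ScheduleSet:
    """Assemble the default schedules (annual beta values converted to monthly)."""
    beta_annual = DEFAULT_BETA_ANNUAL if beta_annual is None else beta_annual
    return ScheduleSet(
        beta_by_year={y: v / 12 for y, v in beta_annual.items()},
        upsilon_by_year=dict(DEFAULT_UPSILON if upsilon_by_year is None else upsilon_by_year),
        tau_by_quarter=dict(DEFAULT_TAU if tau_by_quarter is None else tau_by_quarter),
        prevented_ramp=prevented_ramp or PreventedRamp(),
        prevented_overrides=dict(prevented_overrides or {}),
        start_year=start_year,
    )


def zero_prevention(schedules: ScheduleSet) -> ScheduleSet:
    """Return a copy with the intervention effect removed (prevented = 0 everywhere)."""
    return dataclasses.replace(
        schedules,
        prevented_ramp=PreventedRamp(end_value=0.0),
        prevented_overrides={},
    )


def extend_fentanyl(schedules: ScheduleSet, mode: str, target_year: int) -> ScheduleSet:
    """Extend the fentanyl proxy through ``target_year``.

    ``mode='same'`` carries the last observed value forward; ``mode='trend'``
    extrapolates an ordinary-least-squares line fitted through all observed
    (year, upsilon) pairs. The beta schedule is extended alongside by
    carrying its last value forward, so extended horizons stay simulable.
    """
    if mode not in ("same", "trend"):
        raise ConfigError(f"unknown fentanyl extension mode: {mode!r}")
    ups = dict(schedules.upsilon_by_year)
    last = max(ups)
    if mode == "trend":
        if len(ups) < 2:
            raise ConfigError("trend extension needs at least 2 observed years")
        years = np.array(sorted(ups), dtype=float)
        slope, intercept = np.polyfit(years, [ups[int(y)] for y in years], 1)
    for year in range(last + 1, target_year + 1):
        ups[year] = ups[last] if mode == "same" else float(intercept + slope * year)

    beta = dict(schedules.beta_by_year)
    for year in range(max(beta) + 1, target_year + 1):
        beta[year] = beta[max(schedules.beta_by_year)]
    return dataclasses.replace(schedules, upsilon_by_year=ups, beta_by_year=beta)


def extend_prevention(
    schedules: ScheduleSet,
    mode: str,
    months: int,
    increment: float = 0.10,
    start_month: int | None = None,
) -> ScheduleSet:
    """Extend the prevented proportion for ``months`` months from ``start_month``.

    ``mode='same'`` holds the value in force just before the extension;
    ``mode='higher'`` holds that value plus ``increment``, capped at 1.0.
    ``start_month`` defaults to the month after the ramp (and any overrides)
    end.
    """
    if mode not in ("same", "higher"):
        raise ConfigError(f"unknown prevention extension mode: {mode!r}")
    if increment < 0:
        raise ConfigError("prevention increment must be non-negative")
    if start_month is None:
        start_month = max(
            [schedules.prevented_ramp.end_month + 1]
            + [m + 1 for m in schedules.prevented_overrides]
        )
    last = schedules.prevented(start_month - 1)
    level = last if mode == "same" else min(last + increment, 1.0)
    overrides = dict(schedules.prevented_overrides)
    for m in range(start_month, start_month + months):
        overrides[m] = level
    return dataclasses.replace(schedules, prevented_overrides=overrides)
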