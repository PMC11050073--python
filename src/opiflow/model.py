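"""Core compartmental state, monthly flows, and the one-month state update.

The model tracks the Canadian population aged 15+ across nine living
compartments — no opioid use, short-/long-term prescription use, previous
long-term use, prescription use not as prescribed (and previous such use),
and non-medical use (and previous such use) — plus three cumulative
mortality sinks. Twenty-five flows move people between compartments each
month; five of them are opioid-overdose deaths. Everything here is pure
computation: time-varying inputs come from :mod:`opiflow.schedules`, file
I/O lives in :mod:`opiflow.config` and :mod:`opiflow.io`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

from .errors import StateError
from .schedules import ScheduleSet

logger = logging.getLogger(__name__)

#: Initial compartment sizes, January 2016 (persons). ``A`` is the total
#: living population; the no-use compartment is derived as A minus the sum
#: of the opioid-use compartments. Previous non-medical use starts empty.
DEFAULT_INITIAL_STOCKS: dict[str, float] = {
    "A": 30_874_000.0,
    "C": 262_170.0,
    "D": 690_594.0,
    "E": 700_000.0,
    "F": 320_256.0,
    "G": 100_000.0,
    "H": 200_000.0,
    "I": 0.0,
}

LIVING_STOCKS = ("B", "C", "D", "E", "F", "G", "H", "I")


@dataclass(frozen=True)
class StockState:
    """Compartment occupancies (persons) at one month.

    ``month_index`` counts months since the model start (0 = January 2016
    by default). ``J``, ``K``, ``L`` are cumulative death tallies: other-cause
    deaths among long-term prescription users, opioid overdose deaths from
    all sources, and other-cause deaths among non-medical users.
    """

    month_index: int
    B: float  # no opioid use
    C: float  # short-term prescription use
    D: float  # long-term prescription use
    E: float  # previous long-term prescription use
    F: float  # prescription use not as prescribed
    G: float  # previous use not as prescribed
    H: float  # non-medical use
    I: float  # previous non-medical use
    J: float = 0.0
    K: float = 0.0
    L: float = 0.0

    @property
    def A(self) -> float:
        """Total living population: the sum of the eight living stocks."""
        return self.B + self.C + self.D + self.E + self.F + self.G + self.H + self.I

    @property
    def living(self) -> tuple[float, ...]:
        return tuple(getattr(self, s) for s in LIVING_STOCKS)

    def validate(self) -> None:
        for name in LIVING_STOCKS + ("J", "K", "L"):
            if getattr(self, name) < 0:
                raise StateError(f"stock {name} is negative: {getattr(self, name)!r}")

    @classmethod
    def initial(
        cls, stocks: dict[str, float] | None = None, month_index: int = 0
    ) -> "StockState":
        """Build the starting state from a total population and use stocks.

        ``stocks`` holds ``A`` (total living population) and the opioid-use
        compartments ``C``–``I``; the no-use compartment ``B`` is the
        remainder.
        """
        s = dict(DEFAULT_INITIAL_STOCKS if stocks is None else stocks)
        used = s["C"] + s["D"] + s["E"] + s["F"] + s["G"] + s["H"] + s["I"]
        state = cls(
            month_index=month_index,
            B=s["A"] - used,
            C=s["C"], D=s["D"], E=s["E"], F=s["F"], G=s["G"], H=s["H"], I=s["I"],
        )
        state.validate()
        return state


@dataclass(frozen=True)
class ParameterSet:
    """Constant per-month rates and dimensionless factors.

    All rates are monthly. Annual source values are converted by /12 at
    configuration load; this class only ever sees monthly numbers.
    """

    alpha: float      # population increase
    gamma: float      # proportion of new prescriptions that are short-term
    delta: float      # stop rate, short-term prescription use
    epsilon: float    # prescription use -> use not as prescribed
    zeta: float       # stop rate, long-term prescription use
    eta: float        # previous long-term -> new prescription use
    theta: float      # previous long-term -> no use
    iota: float       # all-cause mortality, long-term prescription use
    kappa: float      # use not as prescribed -> non-medical use
    lambda_: float    # start rate of non-medical use from no use
    mu: float         # stop rate, not-as-prescribed and non-medical use
    nu: float         # previous use -> no use (delay to no use)
    xi: float         # restart rate, non-medical / not-as-prescribed use
    omicron: float    # overdose mortality, long-term prescription use
    pi_: float        # overdose mortality, short-term prescription use
    rho: float        # base overdose mortality, not-as-prescribed + non-medical
    sigma: float      # other-cause mortality, non-medical use
    chi: float        # mortality multiplier, use not as prescribed
    psi: float        # mortality multiplier, fentanyl

    _BASE = dict(
        alpha=0.014 / 12, gamma=0.9, delta=0.9, epsilon=0.093 / 12,
        zeta=0.017, eta=0.65 / 12, theta=0.08796 / 12, iota=0.06 / 12,
        kappa=0.065 / 12, lambda_=0.00006 / 12, mu=0.09 / 12, nu=0.028,
        xi=0.20 / 12, omicron=0.0000582769, pi_=0.0000043333, sigma=0.000783,
    )

    @classmethod
    def initial(cls) -> "ParameterSet":
        """Published pre-calibration values (rho=0.000542, chi=1, psi=5)."""
        return cls(rho=0.000542, chi=1.0, psi=5.0, **cls._BASE)

    @classmethod
    def optimized(cls) -> "ParameterSet":
        """RMSE-calibrated values (rho=0.000318, chi=0.1, psi=10)."""
        return cls(rho=0.000318, chi=0.1, psi=10.0, **cls._BASE)

    def with_mortality(self, rho: float, chi: float, psi: float) -> "ParameterSet":
        """Return a copy with the three calibrated mortality parameters replaced."""
        return dataclasses.replace(self, rho=rho, chi=chi, psi=psi)


@dataclass(frozen=True)
class FlowSet:
    """The 25 per-month flow magnitudes (persons/month), one per model equation."""

    pop_increase: float            # (a) A*alpha, enters no-use
    start_short: float             # (b) B*beta*gamma
    stop_short: float              # (c) C*delta
    short_to_nap: float            # (d) C*epsilon/10
    start_long: float              # (e) B*beta*(1-gamma)
    stop_long: float               # (f) D*zeta
    prev_long_to_long: float       # (g) E*eta*(1-gamma)
    prev_long_to_short: float      # (h) E*eta*gamma
    long_to_nap: float             # (i) D*epsilon
    prev_long_to_nouse: float      # (j) E*theta
    long_allcause_death: float     # (k) D*iota
    nap_to_nonmed: float           # (l) F*kappa
    stop_nap: float                # (m) F*mu*2
    prev_nap_to_nouse: float       # (n) G*nu
    restart_nap: float             # (o) G*(xi/2)
    start_nonmed: float            # (p) B*lambda
    stop_nonmed: float             # (q) H*mu
    restart_nonmed: float          # (r) I*xi
    prev_nonmed_to_nouse: float    # (s) I*nu
    nonmed_allcause_death: float   # (t) H*sigma
    long_od_death: float           # (u) D*omicron
    short_od_death: float          # (v) C*pi
    nap_od_death: float            # (w) F*rho*chi*phi*tau
    nonmed_nonfent_od_death: float # (x) H*rho*phi*tau
    nonmed_fent_od_death: float    # (y) H*rho*psi*upsilon*phi*tau

    @property
    def overdose_deaths(self) -> float:
        """Total opioid overdose deaths this month (flows u+v+w+x+y)."""
        return (
            self.long_od_death
            + self.short_od_death
            + self.nap_od_death
            + self.nonmed_nonfent_od_death
            + self.nonmed_fent_od_death
        )

    @property
    def total_deaths(self) -> float:
        """All deaths this month: overdose plus the two other-cause flows."""
        return self.overdose_deaths + self.long_allcause_death + self.nonmed_allcause_death


def compute_flows(
    state: StockState, params: ParameterSet, schedules: ScheduleSet
) -> FlowSet:
    """Evaluate all 25 monthly flows at ``state``.

    The time-varying inputs — prescription-initiation rate beta, fentanyl
    proxy upsilon, intervention survival multiplier phi = 1 - prevented,
    and seasonality tau — are looked up for the state's calendar month.
    Overdose mortality from not-as-prescribed and non-medical use carries
    the phi and tau multipliers; the fentanyl pathway additionally carries
    psi * upsilon.

    Raises :class:`StateError` on a negative stock and
    :class:`ScheduleRangeError` if the month is outside schedule coverage.
    """
    state.validate()
    m = state.month_index
    beta = schedules.beta(m)
    upsilon = schedules.upsilon(m)
    phi = schedules.phi_multiplier(m)
    tau = schedules.tau(m)
    p = params

    return FlowSet(
        pop_increase=state.A * p.alpha,
        start_short=state.B * beta * p.gamma,
        stop_short=state.C * p.delta,
        short_to_nap=state.C * p.epsilon / 10,
        start_long=state.B * beta * (1.0 - p.gamma),
        stop_long=state.D * p.zeta,
        prev_long_to_long=state.E * p.eta * (1.0 - p.gamma),
        prev_long_to_short=state.E * p.eta * p.gamma,
        long_to_nap=state.D * p.epsilon,
        prev_long_to_nouse=state.E * p.theta,
        long_allcause_death=state.D * p.iota,
        nap_to_nonmed=state.F * p.kappa,
        stop_nap=state.F * p.mu * 2,
        prev_nap_to_nouse=state.G * p.nu,
        restart_nap=state.G * (p.xi / 2),
        start_nonmed=state.B * p.lambda_,
        stop_nonmed=state.H * p.mu,
        restart_nonmed=state.I * p.xi,
        prev_nonmed_to_nouse=state.I * p.nu,
        nonmed_allcause_death=state.H * p.sigma,
        long_od_death=state.D * p.omicron,
        short_od_death=state.C * p.pi_,
        nap_od_death=state.F * p.rho * p.chi * phi * tau,
        nonmed_nonfent_od_death=state.H * p.rho * phi * tau,
        nonmed_fent_od_death=state.H * p.rho * p.psi * upsilon * phi * tau,
    )


def step(state: StockState, flows: FlowSet) -> StockState:
    """Advance the state one month under forward-Euler bookkeeping.

    Each stock gains its inflows and loses its outflows; the three
    cumulative death sinks accumulate their flows; the month index
    advances. A stock driven below zero is clipped to zero with a logged
    warning — under the default parameters the per-stock outflow fractions
    are below one, so clipping is unreachable and serves only as a guard
    for pathological configurations.
    """
    f = flows
    new = {
        "B": state.B + f.pop_increase + f.stop_short + f.prev_long_to_nouse
             + f.prev_nap_to_nouse + f.prev_nonmed_to_nouse
             - f.start_short - f.start_long - f.start_nonmed,
        "C": state.C + f.start_short + f.prev_long_to_short
             - f.stop_short - f.short_to_nap - f.short_od_death,
        "D": state.D + f.start_long + f.prev_long_to_long
             - f.stop_long - f.long_to_nap - f.long_allcause_death - f.long_od_death,
        "E": state.E + f.stop_long
             - f.prev_long_to_long - f.prev_long_to_short - f.prev_long_to_nouse,
        "F": state.F + f.short_to_nap + f.long_to_nap + f.restart_nap
             - f.nap_to_nonmed - f.stop_nap - f.nap_od_death,
        "G": state.G + f.stop_nap - f.prev_nap_to_nouse - f.restart_nap,
        "H": state.H + f.nap_to_nonmed + f.start_nonmed + f.restart_nonmed
             - f.stop_nonmed - f.nonmed_allcause_death
             - f.nonmed_nonfent_od_death - f.nonmed_fent_od_death,
        "I": state.I + f.stop_nonmed - f.restart_nonmed - f.prev_nonmed_to_nouse,
    }
    for name, value in new.items():
        if value < 0:
            logger.warning(
                "stock %s clipped to 0 at month %d (was %g)",
                name, state.month_index + 1, value,
            )
            new[name] = 0.0

    return StockState(
        month_index=state.month_index + 1,
        J=state.J + f.long_allcause_death,
        K=state.K + f.overdose_deaths,
        L=state.L + f.nonmed_allcause_death,
        **new,
    )
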