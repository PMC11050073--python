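"""RMSE calibration of the three overdose-mortality parameters.

Three parameters are poorly pinned down by external evidence and are fitted
to the quarterly surveillance series instead: the base overdose mortality
rate ``rho``, the not-as-prescribed mortality multiplier ``chi`` and the
fentanyl mortality multiplier ``psi``. The objective is the root mean
squared error between observed and simulated quarterly overdose deaths over
the pre-pandemic window (2016Q1-2019Q4 by default).

The search is a seeded, gradient-free design scan: candidates are drawn
from a scrambled Sobol' sequence over log-scaled boxes (a nested design, so
enlarging the budget can only improve the best RMSE for the same seed), the
current parameter values are always evaluated first, and an optional
Nelder-Mead polish can refine the best point. Identifiability is weak by
construction: not-as-prescribed deaths depend on the product rho*chi and
fentanyl deaths on rho*psi*upsilon, so recovery should be judged on those
products rather than on the raw coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .errors import ConfigError
from .model import ParameterSet, StockState
from .schedules import ScheduleSet
from .simulate import quarterly_deaths, run

#: Search boxes spanning roughly 10x around the pre-calibration values
#: (rho=0.000542, chi=1, psi=5), log-scaled.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rho": (5.42e-5, 5.42e-3),
    "chi": (0.1, 10.0),
    "psi": (0.5, 50.0),
}


@dataclass
class CalibrationResult:
    best_params: tuple[float, float, float]  # (rho, chi, psi)
    best_rmse: float
    n_evaluations: int
    seed: int
    evaluation_log: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=list, repr=False
    )
    polish_evaluations: int = 0

    def to_dict(self) -> dict:
        rho, chi, psi = self.best_params
        return {
            "rho": rho,
            "chi": chi,
            "psi": psi,
            "rmse": self.best_rmse,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "polish_evaluations": self.polish_evaluations,
        }


def rmse_objective(
    candidate: tuple[float, float, float],
    observed: pd.Series,
    params: ParameterSet,
    schedules: ScheduleSet,
    initial: StockState | None = None,
) -> float:
    """RMSE (deaths/quarter) between ``observed`` and the simulated series.

    ``candidate`` is (rho, chi, psi), substituted into ``params``. The model
    is run from ``initial`` for exactly the observed window, which must
    start at the model start and be quarter-aligned.
    """
    if initial is None:
        initial = StockState.initial()
    rho, chi, psi = candidate
    traj = run(initial, params.with_mortality(rho, chi, psi), schedules, 3 * len(observed))
    sim = quarterly_deaths(traj)
    if not sim.index.equals(observed.index):
        raise ConfigError(
            f"observed window {observed.index[0]}..{observed.index[-1]} does not "
            f"match the simulated window {sim.index[0]}..{sim.index[-1]}"
        )
    resid = observed.to_numpy(dtype=float) - sim.to_numpy()
    return float(np.sqrt(np.mean(resid**2)))


def _sobol_candidates(
    n: int, bounds: dict[str, tuple[float, float]], seed: int
) -> np.ndarray:
    log_lo = np.log10([bounds[k][0] for k in ("rho", "chi", "psi")])
    log_hi = np.log10([bounds[k][1] for k in ("rho", "chi", "psi")])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-2 draw sizes
        u = qmc.Sobol(d=3, scramble=True, seed=seed).random(n)
    return 10 ** (log_lo + u * (log_hi - log_lo))


def calibrate(
    observed: pd.Series,
    params: ParameterSet,
    schedules: ScheduleSet,
    budget: int = 10_000,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    polish: bool = False,
    initial: StockState | None = None,
) -> CalibrationResult:
    """Fit (rho, chi, psi) by minimizing the quarterly RMSE.

    Evaluates ``budget`` candidates — the incoming parameter values first,
    then points from a seeded scrambled Sobol' sequence over log-scaled
    ``bounds`` — and returns the argmin. Deterministic given ``seed``.
    With ``polish=True`` a bounded Nelder-Mead refinement is run from the
    best design point; its extra objective evaluations are reported
    separately from the design budget.
    """
    if budget < 1:
        raise ConfigError("calibration budget must be at least 1")
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for key in ("rho", "chi", "psi"):
        lo, hi = bounds.get(key, (0.0, 0.0))
        if not 0 < lo < hi:
            raise ConfigError(f"invalid bounds for {key}: {(lo, hi)}")

    candidates = [(params.rho, params.chi, params.psi)]
    if budget > 1:
        candidates += [tuple(row) for row in _sobol_candidates(budget - 1, bounds, seed)]

    log: list[tuple[tuple[float, float, float], float]] = []
    best_idx = 0
    best_rmse = np.inf
    for i, cand in enumerate(candidates):
        rmse = rmse_objective(cand, observed, params, schedules, initial=initial)
        log.append((cand, rmse))
        if rmse < best_rmse:
            best_rmse, best_idx = rmse, i

    best = candidates[best_idx]
    polish_evals = 0
    if polish:
        log_lo = np.log10([bounds[k][0] for k in ("rho", "chi", "psi")])
        log_hi = np.log10([bounds[k][1] for k in ("rho", "chi", "psi")])

        def objective(z: np.ndarray) -> float:
            cand = tuple(10 ** np.clip(z, log_lo, log_hi))
            rmse = rmse_objective(cand, observed, params, schedules, initial=initial)
            log.append((cand, rmse))
            return rmse

        res = minimize(
            objective, np.log10(best), method="Nelder-Mead",
            options={"maxfev": 200, "xatol": 1e-4, "fatol": 1e-6},
        )
        polish_evals = res.nfev
        if res.fun < best_rmse:
            best_rmse = float(res.fun)
            best = tuple(10 ** np.clip(res.x, log_lo, log_hi))

    return CalibrationResult(
        best_params=tuple(float(v) for v in best),
        best_rmse=float(best_rmse),
        n_evaluations=len(candidates),
        seed=seed,
        evaluation_log=log,
        polish_evaluations=polish_evals,
    )
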