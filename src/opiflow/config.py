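"""Configuration schema, validation, and unit conversion.

A single YAML file carries everything a run needs: initial compartment
sizes, the constant rates with explicit unit annotations (``per_year``
values are converted to monthly by /12 at load), the four time-varying
schedules, and the calibration/scenario settings. Validation is strict:
unknown keys are rejected, every model symbol must be present exactly once,
converted rates must lie in [0, 1], and the per-stock total monthly outflow
fraction must not exceed 1 anywhere in the covered horizon (so the
state-update's negative-stock guard can never fire).
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import dataclass

import yaml

from .errors import ConfigError
from .model import ParameterSet, StockState
from .schedules import PreventedRamp, ScheduleSet, build_default_schedules

logger = logging.getLogger(__name__)

RATE_PARAMS = (
    "alpha", "delta", "epsilon", "zeta", "eta", "theta", "iota", "kappa",
    "lambda", "mu", "nu", "xi", "omicron", "pi", "sigma", "rho",
)
DIMENSIONLESS_PARAMS = ("gamma", "chi", "psi")
CALIBRATED_PARAMS = ("rho", "chi", "psi")
ALL_PARAMS = (
    "alpha", "gamma", "delta", "epsilon", "zeta", "eta", "theta", "iota",
    "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "sigma",
    "rho", "chi", "psi",
)
#: YAML key -> ParameterSet field (keywords and shadowed builtins get a suffix).
_FIELD_OF = {"lambda": "lambda_", "pi": "pi_"}

DEFAULT_CONFIG: dict = {
    "initial_stocks": {
        "A": 30_874_000, "C": 262_170, "D": 690_594, "E": 700_000,
        "F": 320_256, "G": 100_000, "H": 200_000, "I": 0,
    },
    "parameters": {
        "alpha": {"value": 0.014, "unit": "per_year"},
        "gamma": {"value": 0.9, "unit": "dimensionless"},
        "delta": {"value": 0.9, "unit": "per_month"},
        "epsilon": {"value": 0.093, "unit": "per_year"},
        "zeta": {"value": 0.017, "unit": "per_month"},
        "eta": {"value": 0.65, "unit": "per_year"},
        "theta": {"value": 0.08796, "unit": "per_year"},
        "iota": {"value": 0.06, "unit": "per_year"},
        "kappa": {"value": 0.065, "unit": "per_year"},
        "lambda": {"value": 0.00006, "unit": "per_year"},
        "mu": {"value": 0.09, "unit": "per_year"},
        "nu": {"value": 0.028, "unit": "per_month"},
        "xi": {"value": 0.20, "unit": "per_year"},
        "omicron": {"value": 0.0000582769, "unit": "per_month"},
        "pi": {"value": 0.0000043333, "unit": "per_month"},
        "sigma": {"value": 0.000783, "unit": "per_month"},
        "rho": {"initial": 0.000542, "optimized": 0.000318, "unit": "per_month"},
        "chi": {"initial": 1.0, "optimized": 0.1, "unit": "dimensionless"},
        "psi": {"initial": 5.0, "optimized": 10.0, "unit": "dimensionless"},
    },
    "schedules": {
        "start_year": 2016,
        # per_year prescription-initiation rates; divided by 12 at load.
        # 2020-2021 hold the last published (2019) value.
        "beta_by_year": {
            2016: 0.0866, 2017: 0.0838, 2018: 0.0810, 2019: 0.0782,
            2020: 0.0782, 2021: 0.0782,
        },
        # fentanyl proxy, 2020 = 1.00; 2019 uses the trend-consistent 0.80
        "upsilon_by_year": {
            2016: 0.25, 2017: 0.48, 2018: 0.61, 2019: 0.80, 2020: 1.00, 2021: 1.22,
        },
        "tau_by_quarter": {1: 1.02, 2: 1.01, 3: 0.95, 4: 0.99},
        "prevented_ramp": {"start_month": 0, "end_month": 47, "end_value": 0.60},
        "prevented_overrides": {},
    },
    "calibration": {
        "budget": 10_000,
        "seed": 0,
        "window_quarters": 16,
        "bounds": {"rho": [5.42e-5, 5.42e-3], "chi": [0.1, 10.0], "psi": [0.5, 50.0]},
    },
    "scenario": {
        "start_month": 69,   # October 2021: five quarters through December 2022
        "horizon_months": 15,
        "prevention_increment": 0.10,
    },
}

_TOP_KEYS = set(DEFAULT_CONFIG)
_OPTIONAL_TOP = {"calibration", "scenario"}


def _require_keys(section: dict, expected: set[str], where: str, optional: set[str] = frozenset()):
    unknown = set(section) - expected
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    missing = expected - optional - set(section)
    if missing:
        raise ConfigError(f"missing key(s) in {where}: {sorted(missing)}")


def _monthly(value: float, unit: str, name: str) -> float:
    if unit == "per_year":
        return value / 12.0
    if unit in ("per_month", "dimensionless"):
        return float(value)
    raise ConfigError(f"parameter {name}: unknown unit {unit!r}")


@dataclass
class ModelConfig:
    """A validated configuration; ``raw`` keeps the as-written (unit-annotated) form."""

    raw: dict

    # -- derived objects -----------------------------------------------------
    def parameter_set(self, variant: str = "optimized") -> ParameterSet:
        """Monthly-rate parameters; ``variant`` picks the calibrated triple."""
        if variant not in ("initial", "optimized"):
            raise ConfigError(f"unknown parameter variant {variant!r}")
        values = {}
        for name, spec in self.raw["parameters"].items():
            raw_value = spec[variant] if name in CALIBRATED_PARAMS else spec["value"]
            values[_FIELD_OF.get(name, name)] = _monthly(raw_value, spec["unit"], name)
        return ParameterSet(**values)

    def schedule_set(self) -> ScheduleSet:
        s = self.raw["schedules"]
        return build_default_schedules(
            beta_annual=s["beta_by_year"],
            upsilon_by_year=s["upsilon_by_year"],
            tau_by_quarter=s["tau_by_quarter"],
            prevented_ramp=PreventedRamp(**s["prevented_ramp"]),
            prevented_overrides=s["prevented_overrides"],
            start_year=s["start_year"],
        )

    def initial_state(self) -> StockState:
        return StockState.initial({k: float(v) for k, v in self.raw["initial_stocks"].items()})

    @property
    def calibration(self) -> dict:
        return self.raw["calibration"]

    @property
    def scenario(self) -> dict:
        return self.raw["scenario"]

    # -- serialisation --------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @property
    def hash(self) -> str:
        """SHA-256 of the canonical YAML form; recorded in every output."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _validate(raw: dict) -> dict:
    raw = copy.deepcopy(raw)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _require_keys(raw, _TOP_KEYS, "config", optional=_OPTIONAL_TOP)
    for key in _OPTIONAL_TOP:
        if key not in raw:
            logger.info("config: using default %s block", key)
            raw[key] = copy.deepcopy(DEFAULT_CONFIG[key])

    stocks = raw["initial_stocks"]
    _require_keys(stocks, {"A", "C", "D", "E", "F", "G", "H", "I"}, "initial_stocks")
    for name, v in stocks.items():
        if v < 0:
            raise ConfigError(f"initial stock {name} is negative")
    if stocks["A"] < sum(stocks[k] for k in "CDEFGHI"):
        raise ConfigError("total population A is smaller than the sum of use stocks")

    params = raw["parameters"]
    _require_keys(params, set(ALL_PARAMS), "parameters")
    for name, spec in params.items():
        value_keys = {"initial", "optimized"} if name in CALIBRATED_PARAMS else {"value"}
        _require_keys(spec, value_keys | {"unit"}, f"parameters.{name}")
        for key in value_keys:
            monthly = _monthly(spec[key], spec["unit"], name)
            if name in DIMENSIONLESS_PARAMS:
                if monthly <= 0:
                    raise ConfigError(f"parameter {name} must be positive")
                if name == "gamma" and not 0 <= monthly <= 1:
                    raise ConfigError("gamma is a proportion and must lie in [0, 1]")
            elif not 0 <= monthly <= 1:
                raise ConfigError(
                    f"parameter {name}: monthly rate {monthly} outside [0, 1]"
                )

    sched = raw["schedules"]
    _require_keys(
        sched,
        {"start_year", "beta_by_year", "upsilon_by_year", "tau_by_quarter",
         "prevented_ramp", "prevented_overrides"},
        "schedules",
    )
    _require_keys(sched["prevented_ramp"], {"start_month", "end_month", "end_value"},
                  "schedules.prevented_ramp")

    cal = raw["calibration"]
    _require_keys(cal, {"budget", "seed", "window_quarters", "bounds"}, "calibration")
    _require_keys(cal["bounds"], {"rho", "chi", "psi"}, "calibration.bounds")
    if cal["budget"] < 1:
        raise ConfigError("calibration budget must be at least 1")

    scen = raw["scenario"]
    _require_keys(scen, {"start_month", "horizon_months", "prevention_increment"}, "scenario")
    if scen["prevention_increment"] < 0:
        raise ConfigError("prevention increment must be non-negative")
    return raw


def _check_outflow_fractions(config: ModelConfig) -> None:
    """Every stock's total monthly outflow fraction must stay at or below 1.

    Checked for both parameter variants across the configured schedule
    coverage; guarantees the forward-Euler update cannot drive a stock
    negative.
    """
    schedules = config.schedule_set()
    years = sorted(set(schedules.beta_by_year) & set(schedules.upsilon_by_year))
    months = [
        (y - schedules.start_year) * 12 + m
        for y in years
        for m in range(12)
        if y >= schedules.start_year
    ]
    for variant in ("initial", "optimized"):
        p = config.parameter_set(variant)
        for m in months:
            beta = schedules.beta(m)
            phi_tau = schedules.phi_multiplier(m) * schedules.tau(m)
            od = p.rho * phi_tau
            fractions = {
                "B": beta + p.lambda_,
                "C": p.delta + p.epsilon / 10 + p.pi_,
                "D": p.zeta + p.epsilon + p.iota + p.omicron,
                "E": p.eta + p.theta,
                "F": p.kappa + 2 * p.mu + od * p.chi,
                "G": p.nu + p.xi / 2,
                "H": p.mu + p.sigma + od * (1 + p.psi * schedules.upsilon(m)),
                "I": p.xi + p.nu,
            }
            for stock, frac in fractions.items():
                if frac > 1.0:
                    raise ConfigError(
                        f"stock {stock}: total monthly outflow fraction {frac:.4f} "
                        f"exceeds 1 at month {m} ({variant} parameters)"
                    )


def default_config() -> ModelConfig:
    return ModelConfig(raw=copy.deepcopy(DEFAULT_CONFIG))


def load_config(path) -> ModelConfig:
    """Load, validate, and unit-check a YAML configuration file."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
    config = ModelConfig(raw=_validate(raw))
    config.schedule_set()          # runs the ScheduleSet invariant checks
    config.initial_state()
    _check_outflow_fractions(config)
    return config
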