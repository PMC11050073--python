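"""Synthetic surveillance-like quarterly death series and test fixtures.

National overdose-death surveillance is distributed as quarterly counts;
this module emulates that series so every pipeline stage is testable
without external downloads. Series are produced by running the model at
known "true" mortality parameters, aggregating quarterly, and applying an
observation-noise model — Poisson by default, since deaths are counts.
At the default parameters the series rises from roughly 600 to 1,100
deaths per quarter over 2016-2019 with mild quarterly seasonality,
matching the scale of the real national series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, default_config
from .errors import ConfigError
from .model import ParameterSet, StockState
from .schedules import ScheduleSet
from .simulate import quarterly_deaths, run, run_counterfactual


@dataclass(frozen=True)
class SynthConfig:
    """Settings for one synthetic series draw."""

    true_params: tuple[float, float, float] = (0.000318, 0.1, 10.0)  # (rho, chi, psi)
    noise_model: str = "poisson"   # 'none' | 'poisson' | 'lognormal'
    noise_scale: float = 0.0       # lognormal sigma; unused otherwise
    seed: int = 1234
    quarters: int = 16

    def __post_init__(self):
        if self.noise_model not in ("none", "poisson", "lognormal"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be non-negative")
        if self.quarters < 1:
            raise ConfigError("need at least one quarter")


def generate_observed(
    config: SynthConfig,
    params: ParameterSet | None = None,
    schedules: ScheduleSet | None = None,
    initial: StockState | None = None,
) -> pd.Series:
    """Simulate at the true parameters and add observation noise. Seeded."""
    model_config = default_config()
    if params is None:
        params = model_config.parameter_set()
    if schedules is None:
        schedules = model_config.schedule_set()
    if initial is None:
        initial = model_config.initial_state()
    rho, chi, psi = config.true_params
    traj = run(initial, params.with_mortality(rho, chi, psi), schedules, 3 * config.quarters)
    clean = quarterly_deaths(traj)

    rng = np.random.default_rng(config.seed)
    if config.noise_model == "poisson":
        values = rng.poisson(clean.to_numpy()).astype(float)
    elif config.noise_model == "lognormal":
        values = clean.to_numpy() * rng.lognormal(0.0, config.noise_scale, len(clean))
    else:
        values = clean.to_numpy()
    return pd.Series(values, index=clean.index, name="deaths")


def make_fixture_bundle(outdir, seed: int = 1234) -> dict[str, Path]:
    """Write a self-contained synthetic test bundle into ``outdir``.

    Produces the default configuration file, a 16-quarter synthetic
    observed series (Poisson noise around the calibrated model's own
    output), and a JSON of model-computed reference quantities for
    regression tests. All contents are recomputed, never hand-entered.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_config = default_config()

    config_path = outdir / "config.yaml"
    model_config.dump(config_path)

    synth = SynthConfig(seed=seed)
    observed = generate_observed(synth)
    observed_path = outdir / "observed_synthetic.csv"
    from .io import write_series_csv

    write_series_csv(observed, observed_path, config_hash=model_config.hash)

    params = model_config.parameter_set()
    schedules = model_config.schedule_set()
    initial = model_config.initial_state()
    baseline = run(initial, params, schedules, 48)
    counterfactual = run_counterfactual(params, schedules, 48, initial=initial)
    expected = {
        "seed": seed,
        "config_sha256": model_config.hash,
        "baseline_total": baseline.cumulative_od_deaths,
        "counterfactual_total": counterfactual.cumulative_od_deaths,
        "excess": counterfactual.cumulative_od_deaths - baseline.cumulative_od_deaths,
        "baseline_quarterly": {
            str(k): float(v) for k, v in quarterly_deaths(baseline).items()
        },
    }
    expected_path = outdir / "expected_synthetic.json"
    expected_path.write_text(json.dumps(expected, indent=2) + "\n")

    return {"config": config_path, "observed": observed_path, "expected": expected_path}
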