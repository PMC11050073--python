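# opiflow

A monthly stock-and-flow model of opioid use and opioid overdose death in
Canada from January 2016, built for public-health analysts and modellers who
need to explore how the overdose crisis might evolve under changing drug
supply and intervention conditions — and what it might have looked like
without the post-2016 response.

## The model

The population aged 15+ is divided into nine living compartments: no opioid
use (B), short-term (C) and long-term (D) prescription use, previous
long-term use (E), prescription use not as prescribed (F) and previous such
use (G), and non-medical use (H) with previous non-medical use (I). Three
cumulative sinks track other-cause deaths among long-term prescription users
(J), opioid overdose deaths from all sources (K), and other-cause deaths
among non-medical users (L). Twenty-five flows — each a per-month rate times
its source stock — move people between compartments in discrete monthly
forward-Euler steps.

Five of the flows are overdose deaths. The prescription-use mortality flows
(D·ο, C·π) are constant-rate; mortality from use not as prescribed and from
non-medical use is modulated by four time-varying inputs:

- **υ(year)** — a fentanyl-penetration proxy for the unregulated supply,
  indexed to 2020 = 1.00, rising from 0.25 (2016) to 1.22 (2021);
- **φ(month) = 1 − prevented(month)** — the survival multiplier from health
  interventions (naloxone distribution, opioid agonist therapy, supervised
  consumption, the Good Samaritan law), with the prevented proportion
  ramping linearly from 0 in January 2016 to 0.60 in December 2019;
- **τ(quarter)** — seasonality multipliers 1.02, 1.01, 0.95, 0.99;
- **β(year)** — an annually declining prescription-initiation rate.

The non-medical fentanyl death flow, for example, is H·ρ·ψ·υ·φ·τ, where ρ is
the base overdose mortality rate and ψ the fentanyl mortality multiplier.
Three mortality parameters (ρ, χ, ψ) are calibrated by minimizing the RMSE
between simulated and observed quarterly death counts over 2016–2019, using
a seeded quasi-random scan of 10,000 candidates over log-scaled bounds.

## Worked example

```sh
python examples/counterfactual_excess_deaths.py
```

```
baseline (with intervention ramp):      15176 overdose deaths
counterfactual (no interventions):      22162 overdose deaths
excess under the counterfactual:         6987 deaths
```

The baseline run reproduces the roughly 15,000 overdose deaths recorded
nationally over January 2016 – December 2019. Re-running the same 48 months
with the intervention effect removed (prevented ≡ 0, so φ ≡ 1) raises the
total toward 22,000: under the model's assumptions — and explicitly not as
a causal estimate — the post-2016 response averted on the order of 7,000
deaths over the first four years of the crisis.

Other examples: `baseline_quarterly_fit.py` (the 16-quarter calibrated
series), `covid_scenarios.py` (four 15-month projections from October 2021
crossing held/raised intervention effect with held/trending fentanyl, labelled
HI1F1 … HI2F2), and `calibrate_to_synthetic_data.py` (parameter recovery on a
synthetic surveillance series, judged on the identifiable mortality
intensities).

The same operations are available from the shell:

```sh
opiflow simulate --months 48 --out baseline.csv
opiflow counterfactual --outdir cf/
opiflow scenarios --outdir scen/
opiflow calibrate --observed observed.csv --budget 10000 --seed 0 --out fit.json
opiflow synth --seed 1234 --outdir fixture/
```

Every output records the SHA-256 of the active configuration; identical
config and seed reproduce byte-identical files.

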