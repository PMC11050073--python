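# Methods

## Model structure and assumptions

The model is a deterministic compartmental stock-and-flow system in discrete
monthly time, starting January 2016. Nine living stocks partition the
Canadian population aged 15+ by opioid-use state; three cumulative sinks
absorb deaths. Each of the 25 flows is a source stock times a per-month
rate, evaluated at the current month and applied with a forward-Euler update
(Δt = 1 month, no ODE solver). A continuous-time reinterpretation would not
be faithful here: the short-term prescription stop rate is 0.9/month, large
enough that exp(-rate) and 1-rate differ materially, and all published rates
are quoted per month.

Key structural assumptions:

- New people enter the population (at rate α, into the no-use stock only)
  and leave solely through the five modelled death flows; there is no
  emigration or background mortality outside the at-risk stocks, so total
  living population A is maintained as the sum of the living stocks and the
  monthly inflow A·α grows with it.
- People stopping short-term prescription use return directly to no use.
  The "previous use" stocks (previous long-term prescription, previous
  not-as-prescribed, previous non-medical) model a delay during which people
  remain at high risk of resuming use; their exits to no use are governed by
  θ (previous long-term) and ν (the other two).
- Overdose mortality from prescription use (long-term D·ο, short-term C·π)
  is constant over the model period. Mortality from use not as prescribed
  and non-medical use shares a base rate ρ, scaled by the multipliers χ
  (not-as-prescribed), ψ·υ (fentanyl pathway), the intervention survival
  multiplier φ, and seasonality τ.
- The flow update order within a month is simultaneous: all flows are
  computed from the start-of-month state, then applied together.

### Flow routing

Inflows/outflows per stock (letters are the flow labels used in the code's
comments): B gains the population inflow (a) and the returns to no use
(c, j, n, s) and loses prescription starts (b, e) and non-medical starts
(p); C gains (b, h) and loses (c, d, v); D gains (e, g) and loses
(f, i, k, u); E gains (f) and loses (g, h, j); F gains (d, i, o) and loses
(l, m, w); G gains (m) and loses (n, o); H gains (l, p, r) and loses
(q, t, x, y); I gains (q) and loses (r, s). Deaths (k → J; u, v, w, x, y →
K; t → L) leave the living population. Mass balance — the change in total
living population equals the inflow minus the five death flows — holds to
1e-9 relative tolerance and is asserted over 120-month runs.

## Parameters

All rates are per month after load-time conversion (annual values divided
by 12); the configuration file requires an explicit `per_year` / `per_month`
/ `dimensionless` annotation on every parameter.

| symbol | meaning | default (monthly) |
|---|---|---|
| α | population increase | 0.014/12 ≈ 0.00117 |
| γ | share of new prescriptions that are short-term | 0.9 |
| δ | stop rate, short-term use | 0.9 |
| ε | prescription use → not as prescribed | 0.093/12 (short-term uses ε/10) |
| ζ | stop rate, long-term use | 0.017 |
| η | previous long-term → renewed prescription use | 0.65/12 ≈ 0.0542 |
| θ | previous long-term → no use | 0.08796/12 |
| ι | all-cause mortality, long-term use | 0.06/12 |
| κ | not-as-prescribed → non-medical | 0.065/12 |
| λ | no use → non-medical | 0.00006/12 |
| μ | stop rate, not-as-prescribed (×2) and non-medical | 0.09/12 |
| ν | previous-use delay to no use | 0.028 |
| ξ | restart, non-medical (not-as-prescribed uses ξ/2) | 0.20/12 |
| ο | overdose mortality, long-term use | 5.82769e-5 |
| π | overdose mortality, short-term use | 4.3333e-6 |
| ρ | base overdose mortality, not-as-prescribed + non-medical | 0.000542 initial; 0.000318 calibrated |
| σ | other-cause mortality, non-medical use | 0.000783 |
| χ | not-as-prescribed mortality multiplier | 1 initial; 0.1 calibrated |
| ψ | fentanyl mortality multiplier | 5 initial; 10 calibrated |

Two published values required a resolution, both selectable in the
configuration:

- **η** is quoted inconsistently (0.65 per year alongside 0.55 per month);
  the package defaults to the /12 conversion (≈0.0542/month) used for every
  other annual rate. 0.55/month would empty the previous-long-term stock in
  under two months, which contradicts its role as a delay state.
- **υ(2019)** is printed as 0.08, breaking the otherwise monotone proxy
  series 0.25, 0.48, 0.61, ·, 1.00, 1.22 and collapsing simulated 2019
  deaths far below the fitted series; the default uses the trend-consistent
  0.80 (a presumed dropped zero).

The prescription-initiation rate β is published for 2016–2019 only; the
default schedule holds the 2019 value through 2021 so that scenario
baselines (which run to October 2021) remain simulable. The prevented
proportion is held at its 0.60 endpoint after December 2019 unless
overridden per month; its within-ramp interpolation is linear in the month
index with exact endpoints at months 0 and 47.

## Calibration

The objective is RMSE between observed and simulated quarterly overdose
deaths over the 16 pre-pandemic quarters. The search evaluates a fixed
budget (default 10,000) of candidates: the incoming parameter values first,
then a scrambled Sobol' sequence over log-scaled boxes spanning roughly 10×
around the pre-calibration values. A quasi-random sequence was chosen over
a Latin hypercube because it is prefix-nested — for a fixed seed, a larger
budget evaluates a strict superset of candidates, so the best RMSE is
monotone in the budget, which the tests assert. An optional Nelder-Mead
polish (off by default) refines the best point in log space.

**Identifiability.** Overdose deaths constrain only two combinations of the
three calibrated parameters. The fentanyl flow H·ρ·ψ·υ·φ·τ identifies the
intensity ρ·ψ (given the υ schedule); the not-as-prescribed flow F·ρ·χ·φ·τ
and the non-fentanyl flow H·ρ·φ·τ share the same φ·τ modulation and their
source stocks evolve almost independently of the candidate, so only the
combined intensity F·ρχ + H·ρ is identifiable — not ρ·χ or ρ alone. A
simulation study (2% multiplicative noise, 10,000-candidate budget) recovers
ρ·ψ within a few percent and F·ρχ + H·ρ within ~15% across seeds, while the
raw coordinates wander by factors of 2–5 along the compensating ridge:
moving 50% along that ridge changes the noise-free RMSE by about 1
death/quarter against a ~16 deaths/quarter noise floor. Recovery is
therefore asserted on the identifiable intensities, and a dedicated test
demonstrates the ridge flatness.

## Scenarios and counterfactual

Four scenarios project 15 months (five quarters) from the baseline state at
a quarter boundary (default October 2021, month 69): the prevented
proportion either holds its last value or steps up by a configurable
increment (default +0.10, capped at 1.0), crossed with the fentanyl proxy
either holding its last value or following the ordinary-least-squares trend
through all observed years (which puts υ(2022) at ≈1.39). With a positive
increment and a rising trend the quarterly series obey the envelope ordering
HI2F1 ≤ {HI1F1, HI2F2} ≤ HI1F2. The higher-intervention increment is a
modelling choice, not a published value. Because the post-2019 prevented
path is held rather than re-fitted to pandemic-era surveillance, scenario
outputs are structural projections, not digit-level reproductions of the
published projection figures.

The zero-intervention counterfactual re-runs January 2016 – December 2019
with prevented ≡ 0. At the calibrated parameters it yields ≈22,160
cumulative overdose deaths against ≈15,180 for the baseline — an excess of
≈6,990 — consistent with the published "just under 21,500", "just under
15,000" and "additional 6,500" to within 1–8%, the residual reflecting the
unpublished month-by-month intervention schedule and the υ(2019) resolution.

## Synthetic surveillance data

The generator stands in for the national quarterly surveillance series: it
runs the model at specified "true" (ρ, χ, ψ), aggregates to quarters, and
applies observation noise — Poisson by default (deaths are counts; at
600–1,100 deaths/quarter this is 3–4% relative noise), or multiplicative
lognormal with configurable σ, or none. What it emulates: the national
count scale, the rising trend, and quarterly seasonality. What it does not:
reporting lags and revisions, provincial heterogeneity, the pandemic-era
level shift, and any non-opioid substances. Passing tests therefore
demonstrate internal consistency of the pipeline at realistic scales, not
fidelity to the real series' error structure.

## Numerical choices and degenerate inputs

- Deterministic throughout; the only randomness is the seeded synthetic
  noise and the seeded calibration design, both via numpy Generators.
- Stocks are floats (persons); the state update clips a negative stock to
  zero with a logged warning, but configuration loading enforces per-stock
  total outflow fractions ≤ 1 across the covered horizon (for both parameter
  variants), so the guard is unreachable for any loadable configuration and
  tests assert it never fires.
- Quarterly aggregation requires a quarter-aligned start; a partial trailing
  quarter is dropped with a warning.
- Written death counts are rounded to 2 decimals (the model is continuous);
  cumulative totals are additionally reported as integers for comparison
  with published figures.
- Degenerate inputs: a zero state yields zero flows; a zero-month run
  returns only the initial state; calibration with budget 1 evaluates
  exactly the incoming parameter values.

## Problem sizes

Default analyses are desk-scale: 48-month runs (~1 ms each), 120-month
property checks, and a 10,000-evaluation calibration (~15 s on one core).
The test suite and the acceptance script complete in well under a minute.

## Limitations

National aggregate only — no age, sex, gender, or regional stratification;
no causal interpretation of the intervention-effect schedule, which was
constructed to reconcile modelled and observed deaths; constant prescription
mortality rates; annual resolution on the fentanyl proxy; and the structural
non-identifiability of (ρ, χ) documented above, which any reuse of the
calibrated raw coordinates should respect.
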