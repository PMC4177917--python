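# Methods

## Scope and units

The package computes pharmaceutical mass balances around a wastewater
treatment plant (WWTP) and along a receiving river network. Canonical
units, used everywhere and converted only in `wbe.units`:

| quantity | unit |
|---|---|
| concentration | ng/L |
| WWTP / river flow | m³/h (hourly), m³/d (daily) |
| mass load | mg/h, mg/d |
| per-capita load | µg/cap/d |
| prescribed mass | g |

Hourly load = concentration × flow / 1000 (ng/L × m³ = µg). Per-capita
load = daily load × 1000 / population.

## Censoring

Concentrations below an analyte's limit of quantification (LOQ) are
left-censored. The storage layer keeps them as a flag only — never as 0 or
LOQ/2 — so that any substitution is a visible analysis choice. Daily-load
aggregation substitutes censored hours under a named policy: `zero`
(default), `half_loq` or `loq`. The default makes daily loads conservative
lower bounds; the three policies are ordered (`zero` ≤ `half_loq` ≤ `loq`)
on any input, which bounds the sensitivity of a load to the censoring
convention. Mean and standard deviation of concentration are computed over
the uncensored samples only ("mean above LOQ"), the convention monitoring
campaigns print alongside detection counts. Maximum-likelihood censored
estimators (Kaplan–Meier, regression on order statistics) are deliberately
out of scope: the above-LOQ mean is the quantity being reproduced.

Timestamps are ISO 8601 local clock time; an hourly sample stamped 18:00
represents the preceding hour (17:00–18:00). Autosampler conventions vary
and the choice is arbitrary, but fixing it makes maximum-load hours
reproducible.

## Removal mass balance

Percent loss across the works is the signed relative change in 24-h load,
100·(influent − effluent)/influent. Influent and effluent are sampled
simultaneously over the same day, so no travel-time lag correction is
applied — the estimate assumes drug use and hydraulic retention change
negligibly between the two days the water actually represents. Negative
values are reported as such (an apparent in-plant increase, e.g. from
deconjugation or desorption); an influent entirely below the LOQ with a
quantified effluent yields a sentinel rendered "<" rather than a number.
Display rounding is to the nearest integer percent; full precision is kept
on the result objects.

## Forward prescription model

Predicted influent concentration: C_w = M·E·F/(P·L), with predicted
excreted mass M·E·F·1000 mg/d. Parameters:

* **M** — daily prescribed mass (g/d). Monthly, spatially resolved
  statistics are divided by their period length directly. Annual national
  statistics are first winter-adjusted: M = Mₐ(1 + 0.09375), i.e. half of
  the ~18.75% summer/winter swing in UK antibiotic consumption, then
  divided by 365. Statistics in ADQ counts convert via the analyte's ADQ
  mass. Co-trimoxazole splits into 0.16 g trimethoprim + 0.8 g
  sulfamethoxazole per ADQ.
* **E** — excreted bioactive fraction, from the packaged analyte panel.
* **F** — catchment correction: population served by the WWTP divided by
  the population covered by the prescription statistics; 1 for national
  statistics. For the small-catchment configuration used in tests,
  6,230/16,000 = 0.389.
* **P·L** — catchment population × per-capita wastewater volume
  (default 230 L/cap/d).

No molar-mass correction is applied between a prodrug and its excreted
metabolite; only E is applied. For oseltamivir → oseltamivir carboxylate
this matches standard practice (E = 0.80 already expresses the conversion);
the knob exists in the data model (adjust E) rather than as a separate
factor.

## Back-estimation and compliance

users = (load/1000)/(dose·E). Users are real numbers, not rounded counts —
a small catchment legitimately yields ~3 user-equivalents, and rounding
would hide the scale of the sampling error. Compliance is estimated users
divided by surveillance-predicted users (population × rate). Two rates are
packaged: the national pandemic-flu-service antiviral collection rate
(0.13% per week) as default, and the syndromic influenza-like-illness rate
(54.2 per 100,000) as an alternative; both are exposed so the ~40% swing
between surveillance sources can be propagated as a sensitivity range.

## Synthetic-data generator

The generator emulates the sampling design the analysis assumes, with an
exactly recorded ground truth (`SimTruth`):

* **Diurnal flow.** 24 hourly flows whose total is exactly P·L; the shape
  is a fixed zero-mean bimodal profile (morning peak 07:00–09:00, evening
  18:00–22:00) scaled by `diurnal_amplitude` ∈ [0, 1). Amplitude 0 is flat.
* **Flush pulses.** Each analyte's daily excreted mass (n_users × dose × E)
  reaches the sewer as discrete toilet-flush events: a Poisson number of
  pulses with mean n_users × flushes/user (default 4/d), placed into hours
  by a diurnal toilet-use profile. The day's mass is split equally over the
  realised pulses, so the daily mass balance is exact by construction while
  few-user catchments still show lumpy hour-to-hour loads — the
  small-catchment sampling-error effect that inflates the hourly coefficient
  of variation. A zero-pulse draw against a nonzero mass is bumped to one
  pulse (the mass must reach the sewer some hour). Dividing by the realised
  rather than the expected pulse count is a deliberate choice: it trades a
  slightly narrower day-to-day total-mass distribution for an exact
  noise-free conservation law that downstream recovery tests can use as an
  oracle.
* **Noise.** Multiplicative lognormal with mean 1 and configurable
  coefficient of variation (concentrations are positive and right-skewed;
  additive Gaussian noise would break positivity). `noise_cv = 0` disables
  it exactly.
* **Effluent.** Hourly influent load shifted circularly within the day by
  the hydraulic retention time (influent and effluent are sampled
  simultaneously over the same 24 h), attenuated by a per-analyte removal
  fraction, re-noised and re-censored.
* **River network.** Sites ordered downstream with nondecreasing upstream
  populations; a site's daily load is the upstream per-capita excreted load
  (after WWTP removal) × upstream population, diluted into the site's daily
  mean flow; one noised grab sample per date, censored at the LOQ. No
  in-river decay, travel-time routing or sediment partitioning is modelled:
  a grab sample stands for the whole day.

What the generator does **not** emulate: rainfall/infiltration dynamics,
within-day river concentration dynamics, correlated multi-analyte excretion,
pharmacokinetic time courses after dosing, or plant upsets. Passing
recovery tests on synthetic data therefore demonstrates that the estimators
are consistent under the stated sampling model, not that real campaigns are
free of the biases those unmodelled features introduce.

## Default study conditions in tests

Recovery tests use a small catchment of 6,230 people and a large one of
50,000–208,000 at 230 L/cap/d; antiviral dosing 0.150 g/d with E = 0.80;
noise_cv 0.1 for WWTP recovery (50 replicate days), 0.2 for river
regression (8 sites spanning 5,000–1.5 M upstream population, 50 seeds).
These sizes keep the full suite under a few seconds while giving Monte-Carlo
means tight enough for the stated tolerances (user recovery within 10%,
removal within 3 percentage points, median R² ≥ 0.8).

## Numerical choices

* Ordinary least squares for the population–load regression
  (`scipy.stats.linregress`), uncensored sites only, undefined below 3
  points.
* Percent loss, per-capita loads and mean concentrations are rounded only
  at the rendering layer (integer ng/L and percent, 3 significant figures
  for loads); machine-readable CSVs keep full precision.
* Deterministic seeding throughout: one `numpy` `default_rng` per
  simulation, with effluent and river draws derived from the seed via
  `SeedSequence` so identical configurations are byte-identical and
  independent stages do not share streams.
* Degenerate inputs fail loudly: zero population, zero flow against nonzero
  mass, negative concentrations, misaligned sample/flow hours, fewer than
  24 hours without an explicit allow-gaps flag (which renormalises by the
  covered fraction).

## Known limitations

* The above-LOQ mean is biased high as a concentration summary under heavy
  censoring; it is reported because it is the field's printed convention,
  with detection counts alongside.
* Back-estimation assumes steady-state daily balance and full compliance
  with the assumed dose; deviations fold into the user count.
* The effluent model applies a single removal fraction per analyte; real
  plants show flow- and temperature-dependent removal.
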