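# Methods

`hydrocast` models the daily water level of rain-fed ephemeral wetlands and
projects it under climate scenarios to score breeding-habitat suitability
for the flatwoods salamander.  This note documents the model, the covariate
computations, the numerical choices, what the synthetic data generator does
and does not emulate, and the problem sizes used by the shipped experiments.

## The water-level model

For one wetland, the mean daily water level `y_t` (mm, positive above the
ground surface) follows a first-order autoregressive regression on climate
covariates:

    y_t = α + β_AR y_{t−1} + β_P P_{t−1} + β_PET PET_t + β_PET² PET_t²
          + β_WP WP_t + β_S S_t + β_PA P_{t−1} y_{t−1} + β_SP S_t P_{t−1}
          + β_SPA S_t P_{t−1} y_{t−1} + ε_t,        ε_t ~ N(0, σ²)

with `P_{t−1}` the previous day's rain (mm), `PET_t` the day's potential
evapotranspiration (mm/day), `WP_t` the rain sum over the previous seven
days (mm), and `S_t` the 12-month SPEI of the day's calendar month.  The
linear-plus-quadratic PET terms capture the nonlinear response of drawdown
at low atmospheric demand; the `P:AR` interaction makes the effective rain
response stage-dependent; the SPEI terms modulate both baseline level and
rain response under long-term drought or wet spells.  Eleven parameters
(ten coefficients and σ²) are estimated per wetland; wetlands are fitted
independently — no pooling.

All regressors are strictly lagged or same-day exogenous quantities, so
one-step-ahead prediction is causal.  The 7-day window is days `t−7…t−1`,
excluding day `t`, consistent with `P` being previous-day rain.

### Priors and sampling

Coefficients get vague N(0, 100) priors; the error variance a Uniform(0,
100) prior, read literally as a prior on the *variance*.  Because the
likelihood is linear-Gaussian, the posterior is sampled by an exact
two-block Gibbs scheme:

* `β | σ², y` — the conjugate multivariate-normal update, drawn through an
  eigendecomposition of `X'X` (computed once per fit) so each iteration
  costs O(p²);
* `σ² | β, y` — an inverse-gamma-shaped conditional (shape `n/2 − 1`, scale
  `SSE/2`) truncated to the uniform prior's support, drawn by rejection
  from the untruncated law with an inverse-CDF fallback.  A truncation
  region with essentially no posterior mass is reported as an error rather
  than silently pinned.

No adaptation phase exists (nothing is tuned); an `n_adapt` config value is
accepted for compatibility and ignored with a log notice.

The default `McmcConfig` is 3 chains × 400,000 iterations, 300,000 burn-in,
thinning 100 — which retains 1,000 draws per chain (3,000 total).  Reports
of this sampler configuration elsewhere pair the same knobs with "2,000
retained per chain (6,000 total)"; the two statements are arithmetically
inconsistent, so this package keeps the literal knob values and exposes all
of them.  The shipped experiments use a reduced configuration (see problem
sizes below) that retains 6,000 draws.

A caution on the variance prior: Uniform(0, 100) on σ² caps the residual SD
at 10 mm.  Wetlands whose residual scale exceeds that (including the
package's default synthetic well, σ = 20 mm) need a wider bound or the
sampler aborts with the zero-truncation-mass error; the synthetic
experiments therefore use `variance_prior_hi = 10,000` (σ up to 100 mm).
A vague variance prior must cover the plausible residual scale of the data.

Optional mean-centering of the design columns (`center=True`) improves
conditioning; draws are mapped back to the raw parameterization, so results
are unchanged statistically.  Off by default, as fitting is done on raw
covariates.

### Diagnostics

* **R-hat** — the classic Gelman–Rubin potential scale reduction factor
  from between/within-chain variances (not the rank-normalized split
  variant; the two agree near 1).
* **Bayesian p-value** — posterior predictive check with the χ²-type
  discrepancy `T = Σ((y − Xβ)/σ)²`: per retained draw, replicate data are
  simulated from the fitted likelihood and `p = P(T_rep ≥ T_obs)`.  Values
  near 0.5 indicate self-consistency; near 0 or 1, misfit.
* **95% HPD intervals** — shortest sorted-sample window containing 95% of
  draws; a coefficient is flagged "significant" when its interval excludes
  zero.

## Climate covariates

* **Extraterrestrial radiation** from standard solar geometry (inverse
  Earth–Sun distance, solar declination, sunset hour angle), converted to
  equivalent evaporation at 2.45 MJ m⁻² mm⁻¹.  Latitudes with polar night
  (|φ| ≥ 66.5°) are out of scope and rejected.
* **Daily PET** by Hargreaves–Samani:
  `PET = 0.0023 · Ra · (T_mean + 17.8) · √(T_max − T_min)`, clipped at 0.
* **Monthly PET** by the Hargreaves formula on monthly-mean temperature
  extremes, with Ra at the mid-month day, scaled by days in month.
* **SPEI** — for each month the trailing k-month (default 12) sum of the
  climatic water balance `D = P − PET` is standardized against a
  three-parameter log-logistic distribution fitted *per calendar month*
  over the calibration years by unbiased-PWM L-moments, then mapped through
  the standard-normal quantile.  Numerical choices: the CDF is clipped to
  [1e−6, 1 − 1e−6] before the probit so index values stay finite; samples
  whose third L-moment is negative (possible by chance in near-symmetric
  balance series) are fitted on the reflected sample with
  `F(x) = 1 − F_refl(−x)`; constant or too-short windows raise an error
  rather than returning silent zeros.  A day's SPEI is the value of the
  window ending in its own calendar month.  At least ~20 calibration years
  are recommended for a stable fit.
* **Precipitation features** — previous-day rain, the 7-day sum above, and
  days-since-rain (threshold: any rain > 0 mm; +inf before the first event
  on record).  Days-since-rain is reported for completeness but is not a
  model regressor.

Rows with any undefined regressor (record edges, the first 11 SPEI months)
are dropped and counted.

## Validation protocol

The record is split into one consecutive training block of 75% of the rows,
starting at a position drawn uniformly within the first 25%; the test set is
the complement (possibly two blocks).  Per posterior draw:

* **NRMSE** — RMSE of the mean prediction divided by the range of all
  measured levels in the basin;
* **wet/dry accuracy** — a day is flooded iff level > 0 mm (a tie at
  exactly 0 counts as dry); the proportion of days classified correctly,
  plus the two directional error percentages over all test days.

Test predictions use the observed previous-day level in the AR term by
default (one-step-ahead), which keeps per-day accuracy well defined on a
test block that precedes training in time.  A free-running mode (recursing
on the model's own predictions within each contiguous test block) is
available as a flag and is the harder task; both are reported by the
acceptance script.

## Projection and suitability

Forward simulation runs the fitted equation recursively per posterior draw
over a scenario climate: the AR input of day `t` is the *predicted* level
of day `t−1`.  Process noise (per-day N(0, σ²_draw)) is **included by
default**: hydroperiod run lengths are nonlinear functionals of the
trajectory, and suppressing noise biases them; a flag disables it.  The
initial level is the ground surface (0 mm), with the scenario's lead months
doubling as spin-up — AR memory decays within months for β_AR < 1.  The
scenario must carry at least 12 months of climate before the first reported
day so SPEI-12 is defined; SPEI is calibrated on a supplied baseline window
or, by default, on the scenario's own period.  Projected levels are
unbounded, matching the linear model; an optional floor emulates finite
well depth.

Breeding seasons run 1 November–31 May (212 days, 213 when February of the
ending year is leap), labelled by the starting calendar year; partial
seasons at the record edges are excluded and counted.  Per season and draw:

* **maximum hydroperiod** — the longest run of consecutive days with level
  > 0 mm (ties broken by the earliest run);
* **fill day** — the 0-based offset of that run's start from 1 November
  (defined as the start of the *maximum* run, not the season's first wet
  day);
* **suitable** — maximum hydroperiod ≥ 105 days (15 weeks, a conservative
  larval-development requirement; reported biological extremes are 77–126
  days, and the threshold is configurable).

Across draws, persistence risk is summarized by the median count of
suitable seasons over the horizon and the proportion of draws with ≥ 5
consecutive unsuitable seasons, evaluated per draw over the full horizon.
A wetland is flagged at risk when that proportion exceeds 0.75 or the
median suitable count falls below 15.

## Synthetic data

The generator emulates a humid subtropical site (Gulf Coastal Plain,
30.5 °N): rain occurrence is a two-state Markov chain with monthly
stationary probabilities (winter frontal rain, drier spring/autumn, a
convective summer peak) and lag-1 occurrence correlation 0.3; wet-day
amounts are Gamma(0.8, 17 mm) (~1,600 mm/yr over ~120 wet days);
temperature is a sinusoid (mean 19.5 °C, half-amplitude 7.5 °C, peak
~20 July) with iid daily anomalies (SD 2 °C) and a 10 °C mean diurnal
range.  Scenario variants overlay a linear warming trend (°C/decade) and a
multiplicative precipitation change on the same base draws.  Water levels
are generated from the model equation itself with default parameters tuned
once to yield an ephemeral regime (winter flooding for weeks to months,
spring drawdown, daily recession ~5–15 mm, σ = 20 mm).

What the generator does **not** emulate: spatial heterogeneity across rain
gauges (one climate series serves a well), temperature autocorrelation
weather regimes, well-bottom censoring (available as an optional floor, off
by default), basin-specific storage geometry, and any model misspecification
— levels are generated from the same equation that is fitted.  Passing
tests therefore demonstrate that the pipeline recovers what it assumes and
that its operators are correct, not that the equation is an adequate
description of any particular real wetland.

Leap days are generated, so both breeding-season lengths (212/213 days)
occur.

## Problem sizes in the shipped experiments

The tests and the acceptance script run a deliberately desk-scale version
of the study: a 42-year synthetic climate; one monitoring well with 1,500
fitted days; a reduced sampler of 3 chains × 20,000 iterations (2,000
burn-in, thinning 9; 6,000 retained draws) for headline fits and a single
chain of 20,000 for the 200-replicate coverage experiment; 300 posterior
draws propagated over the 2025–2100 horizon; and a 10-wetland panel
spanning short to long hydroperiod regimes (intercept offsets −12 … +10 mm)
for the suitability-vs-risk relationship.  These sizes were chosen so the
full experiment battery reruns in minutes on one core while keeping
Monte-Carlo error well below every tolerance asserted.

## Known limitations

* The linear-Gaussian form admits arbitrarily negative levels and cannot
  represent bounded storage or overflow; projections inherit this.
* SPEI needs a long climate record; short scenario tables without a
  baseline produce index values standardized against themselves.
* The classic R-hat can miss pathologies that rank-based variants catch;
  with an exact conjugate sampler and overdispersed σ² starts this is not a
  practical concern.
* One SPEI series is accepted per well; within-site gauge heterogeneity is
  out of scope.
* Risk thresholds (105 days, 5 years, 0.75/15) are biological conventions
  exposed as configuration, not estimated quantities.
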