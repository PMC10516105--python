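# hydrocast

Bayesian hydrologic modelling and climate-scenario forecasting for
ephemeral wetlands, built for conservation questions like: *will this
pond still hold water long enough for flatwoods salamander larvae to
metamorphose in 2080?*

Ephemeral (seasonally flooded) wetlands in the pine flatwoods of the
southeastern US are the breeding habitat of the endangered flatwoods
salamander (*Ambystoma bishopi*).  Eggs laid in dry basins hatch when
autumn–winter rain floods the basin, and larvae need roughly 15 consecutive
flooded weeks to reach metamorphosis, so population persistence hinges on
the timing and duration of flooding between 1 November and 31 May.
`hydrocast` fits a per-wetland statistical model of daily water level to
monitoring data, validates it, and propagates it over daily climate
scenarios to score future breeding suitability.

## The model

For one wetland the mean daily water level `y_t` (mm, positive above the
ground surface) follows a Bayesian first-order autoregressive fixed-effect
regression on climate covariates:

```
y_t = α + β_AR·y_{t−1} + β_P·P_{t−1} + β_PET·PET_t + β_PET²·PET_t²
    + β_WP·WP_t + β_S·S_t + β_P:AR·P_{t−1}·y_{t−1} + β_S:P·S_t·P_{t−1}
    + β_S:AR:P·S_t·P_{t−1}·y_{t−1} + ε_t,     ε_t ~ N(0, σ²)
```

where `P` is previous-day rain, `PET` the Hargreaves–Samani potential
evapotranspiration from daily temperature extremes, `WP` the 7-day rain
sum, and `S` the 12-month standardized precipitation–evapotranspiration
index (SPEI, fitted per calendar month by unbiased-PWM L-moments of a
log-logistic).  Priors are vague — N(0, 100) on coefficients, uniform on
the error variance — and the posterior is sampled by an exact two-block
conjugate Gibbs sampler with Gelman–Rubin R̂, a posterior-predictive
Bayesian p-value, and 95% HPD intervals as diagnostics.  Fitted posteriors
are validated on a consecutive 75/25 train/test split (NRMSE and wet/dry
classification) and projected forward per posterior draw; seasonal maximum
hydroperiods, fill dates, and consecutive-reproductive-failure risk are
summarized across the ensemble.

A seeded synthetic-data module (clustered seasonal rainfall, sinusoidal
temperatures, water levels generated from the model equation with known
parameters) makes every stage runnable and testable without any field or
climate-product download.

## Worked example

```python
import numpy as np
import hydrocast as hc
from hydrocast.projection import scenario_covariates

# 42 years of synthetic climate and a monitoring well observed from 2015
climate = hc.generate_climate(hc.ClimateGenConfig(seed=42))
balance = hc.monthly_water_balance(climate, 30.5)
spei_12 = hc.spei(balance, scale=12)
exog = scenario_covariates(climate, 30.5)
exog = exog.loc[exog["date"] >= "2015-01-01"].reset_index(drop=True)
levels = hc.simulate_water_levels(climate, hc.TrueParams(), exog,
                                  init_level=0.0, seed=7)

# covariates -> model -> posterior
cov = hc.build_covariates(levels[["date", "level_mm"]], climate, 30.5, spei_12)
model = hc.WetlandLevelModel.from_covariates(cov)
res = model.fit(
    priors=hc.PriorSpec(variance_prior_hi=10_000),
    mcmc=hc.McmcConfig(n_chains=3, n_iterations=20_000, n_burnin=2_000,
                       thin=9, seed=3),
)
print(res.summary())
```

```
Wetland water-level model (Bayesian AR(1), Gibbs sampler)
  observations: 2921   retained draws: 6000 (3 chains)

parameter                 median    hpd 2.5%   hpd 97.5%    rhat  sig
alpha                    -5.1987    -10.9437      0.4771   1.000
beta_ar                   0.9690      0.9630      0.9755   1.000  *
beta_precip               1.7994      1.7040      1.8945   1.000  *
beta_pet                 -2.8116     -6.2478      0.6235   1.000
beta_pet2                 0.1337     -0.3217      0.6081   1.000
beta_weekprecip           0.0889      0.0623      0.1165   1.000  *
beta_spei                 3.0577      2.0136      4.1578   1.000  *
beta_precip_ar           -0.0007     -0.0012     -0.0002   1.001  *
beta_spei_precip          0.0777     -0.0105      0.1663   1.000
beta_spei_ar_precip       0.0003      0.0000      0.0005   1.000  *
sigma2                  395.3012    375.0011    415.0155   1.000  -

* 95% HPD excludes zero
```

Every chain converged (R̂ ≤ 1.001) and the generating parameters (e.g.
β_AR = 0.97, β_P = 1.8, σ² = 400) sit inside their HPD intervals: daily
rain is the dominant positive driver of stage, PET drives drawdown, and
the level is highly persistent day to day.  Validation and a warm-dry
2025–2100 projection follow:

```python
rep = hc.validate(res, cov, split=hc.SplitSpec(seed=0))
print(f"median train NRMSE: {np.median(rep.train_nrmse):.3f}")
print(f"median test NRMSE:  {np.median(rep.test_nrmse):.3f}")
print(f"median test wet/dry accuracy: {np.median(rep.test_prop_correct):.3f}")

scenario = hc.generate_scenario(
    hc.ClimateGenConfig(seed=77, trend_temp_c_per_decade=0.4,
                        trend_precip_multiplier=0.9),
    range(2024, 2101),
)
ens = hc.project(res.draws, scenario, 30.5, seed=11,
                 draw_indices=np.arange(300), start_date="2025-01-01")
risk = hc.risk_summary(hc.season_table(ens))
print(f"suitable seasons (median over draws): "
      f"{risk.median_suitable_seasons:.0f} of {risk.n_seasons}")
print(f"P(>=5 consecutive failed seasons):    "
      f"{risk.prop_consecutive_failures:.2f}")
print(f"flagged at risk: {risk.at_risk}")
```

```
median train NRMSE: 0.016
median test NRMSE:  0.015
median test wet/dry accuracy: 0.969
suitable seasons (median over draws): 9 of 75
P(>=5 consecutive failed seasons):    1.00
flagged at risk: True
```

One-step prediction errors are under 2% of the basin's level range and
~97% of held-out days are classified correctly as wet or dry; under the
warm-dry scenario this wetland floods for ≥ 105 consecutive breeding-season
days in only a median 9 of 75 future seasons and every posterior draw
contains a ≥ 5-year run of failed seasons — it would be flagged as likely
unsuitable for salamander persistence.

A CLI mirrors the library (`wetland-hydrocast simulate-data | covariates |
fit | validate | project | metrics | run`); `run` executes the whole
pipeline from a TOML config with per-stage manifests and one master seed.

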