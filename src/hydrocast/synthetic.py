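"""Seeded synthetic climate and water-level data.

Every downstream stage (covariates, model fitting, validation, projection,
suitability metrics) is exercised on data from this module, so the pipeline
runs end to end with no external climate products or field records.

The climate generator emulates a humid subtropical site (Gulf Coastal Plain
flatwoods, ~30.5 degN): a seasonal two-state Markov rain-occurrence process
with gamma-distributed wet-day amounts (wet/dry clustering plus a summer
rainfall peak), and a sinusoidal annual temperature cycle with Gaussian daily
anomalies and a fixed-mean diurnal range.  Scenario variants overlay a linear
warming trend and a multiplicative precipitation change on the same base
draws, standing in for downscaled GCM x emission-pathway tables.

Water levels are generated from the same linear first-order autoregressive
model that is later fitted: level_t is a linear function of the previous
day's level, previous-day and 7-day rain, PET and PET^2, SPEI and the three
interaction terms, plus Gaussian noise.  Generating and fitting share one
equation, so parameter recovery is a meaningful check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClimateGenConfig",
    "TrueParams",
    "generate_climate",
    "generate_scenario",
    "simulate_water_levels",
]

# Monthly wet-day probabilities, Jan..Dec: winter frontal rain, a drier
# spring/autumn, and a convective summer peak, as on the Gulf coast.
_DEFAULT_WET_PROB = (
    0.32, 0.32, 0.29, 0.23, 0.26, 0.40, 0.48, 0.45, 0.33, 0.23, 0.27, 0.32,
)


@dataclass(frozen=True)
class ClimateGenConfig:
    """Configuration of the synthetic daily climate generator.

    Defaults describe a Florida-panhandle-like site: ~1,600 mm annual rain
    over ~120 wet days, mean annual temperature 19.5 degC with a 7.5 degC
    seasonal half-amplitude and a 10 degC mean diurnal range.
    """

    n_years: int = 42
    start_year: int = 1981
    latitude_deg: float = 30.5
    wet_day_prob_by_month: tuple = _DEFAULT_WET_PROB
    rain_gamma_shape: float = 0.8
    rain_gamma_scale: float = 17.0  # mm; mean wet-day rain = shape * scale
    wet_persistence: float = 0.3  # lag-1 correlation of rain occurrence
    temp_mean_annual_c: float = 19.5
    temp_seasonal_amplitude_c: float = 7.5
    temp_daily_sd_c: float = 2.0
    diurnal_range_mean_c: float = 10.0
    trend_temp_c_per_decade: float = 0.0
    trend_precip_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.wet_day_prob_by_month, dtype=float)
        numeric = np.array(
            [
                self.latitude_deg,
                self.rain_gamma_shape,
                self.rain_gamma_scale,
                self.wet_persistence,
                self.temp_mean_annual_c,
                self.temp_seasonal_amplitude_c,
                self.temp_daily_sd_c,
                self.diurnal_range_mean_c,
                self.trend_temp_c_per_decade,
                self.trend_precip_multiplier,
            ]
        )
        if probs.shape != (12,) or not np.all(np.isfinite(probs)):
            raise ValueError("wet_day_prob_by_month must be 12 finite values")
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("wet-day probabilities must lie in [0, 1]")
        if not np.all(np.isfinite(numeric)):
            raise ValueError("non-finite value in climate configuration")
        if self.rain_gamma_shape <= 0 or self.rain_gamma_scale <= 0:
            raise ValueError("gamma rain parameters must be positive")
        if self.diurnal_range_mean_c <= 0:
            raise ValueError("diurnal range mean must be positive")
        if not 0 <= self.wet_persistence < 1:
            raise ValueError("wet_persistence must lie in [0, 1)")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


@dataclass(frozen=True)
class TrueParams:
    """Known generating parameters of the water-level equation.

    Units: alpha in mm; beta_ar dimensionless; beta_precip and
    beta_weekprecip in mm stage per mm rain; beta_pet and beta_pet2 in mm per
    (mm/day) and per (mm/day)^2; beta_spei in mm per index unit; interaction
    coefficients in the corresponding products; sigma is the residual SD (mm).

    Defaults are tuned to produce an ephemeral regime at the default climate:
    winters that flood for weeks-to-months and reliable spring draw-down,
    with daily recession of roughly 5-15 mm at typical stages.
    """

    alpha: float = -5.0
    beta_ar: float = 0.97
    beta_precip: float = 1.8
    beta_pet: float = -2.5
    beta_pet2: float = 0.1
    beta_weekprecip: float = 0.08
    beta_spei: float = 3.0
    beta_precip_ar: float = -0.001
    beta_spei_precip: float = 0.1
    beta_spei_ar_precip: float = 0.0003
    sigma: float = 20.0

    def __post_init__(self):
        # sigma = 0 is allowed as the deterministic limit of the recursion
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if abs(self.beta_ar) >= 1:
            raise ValueError("|beta_ar| must be < 1 for stationary generation")

    def as_coefficients(self) -> np.ndarray:
        """Coefficient vector in the model's design-matrix order."""
        return np.array(
            [
                self.alpha,
                self.beta_ar,
                self.beta_precip,
                self.beta_pet,
                self.beta_pet2,
                self.beta_weekprecip,
                self.beta_spei,
                self.beta_precip_ar,
                self.beta_spei_precip,
                self.beta_spei_ar_precip,
            ]
        )


def generate_climate(config: ClimateGenConfig, years: range | None = None) -> pd.DataFrame:
    """Generate a seeded daily climate table (date, precip_mm, tmin_c, tmax_c).

    Covers the calendar years in ``years`` (default
    ``start_year .. start_year + n_years - 1``) including leap days.  The same
    configuration (and seed) always returns an identical table.
    """
    if years is None:
        years = range(config.start_year, config.start_year + config.n_years)
    years = range(min(years), max(years) + 1) if len(years) else years
    if len(years) == 0:
        raise ValueError("empty year range")
    dates = pd.date_range(
        start=f"{years[0]}-01-01", end=f"{years[-1]}-12-31", freq="D"
    )
    n = len(dates)
    rng = np.random.default_rng(config.seed)

    month = dates.month.to_numpy()
    doy = dates.dayofyear.to_numpy()
    pi = np.asarray(config.wet_day_prob_by_month, dtype=float)[month - 1]
    r = config.wet_persistence

    # Two-state Markov occurrence with stationary probability pi_m and lag-1
    # correlation r:  P(wet|wet) = pi + r(1-pi),  P(wet|dry) = pi(1-r).
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    wet[0] = u[0] < pi[0]
    for t in range(1, n):
        p = pi[t] + r * (1.0 - pi[t]) if wet[t - 1] else pi[t] * (1.0 - r)
        wet[t] = u[t] < p
    amounts = rng.gamma(config.rain_gamma_shape, config.rain_gamma_scale, size=n)
    precip = np.where(wet, amounts, 0.0)

    # Annual cycle peaking ~20 July (day 201), iid daily anomalies.
    tmean = (
        config.temp_mean_annual_c
        + config.temp_seasonal_amplitude_c * np.cos(2.0 * np.pi * (doy - 201) / 365.25)
        + rng.normal(0.0, config.temp_daily_sd_c, size=n)
    )
    diurnal = np.maximum(
        rng.normal(config.diurnal_range_mean_c, 0.15 * config.diurnal_range_mean_c, n),
        0.0,
    )
    tmin = tmean - 0.5 * diurnal
    tmax = tmean + 0.5 * diurnal

    return pd.DataFrame(
        {"date": dates, "precip_mm": precip, "tmin_c": tmin, "tmax_c": tmax}
    )


def generate_scenario(config: ClimateGenConfig, years: range) -> pd.DataFrame:
    """Generate a stylized future climate scenario table.

    The base generator runs over ``years`` with the configured seed, then a
    linear temperature trend of ``trend_temp_c_per_decade`` (relative to the
    first scenario year, applied to both extremes) and a multiplicative
    precipitation change ``trend_precip_multiplier`` are overlaid.  With the
    trend knobs at (0, 1.0) the output equals :func:`generate_climate` for the
    same seed and years.
    """
    if len(years) == 0:
        raise ValueError("empty year range")
    base = generate_climate(config, years=years)
    elapsed_years = (
        (base["date"] - base["date"].iloc[0]).dt.days.to_numpy() / 365.25
    )
    warming = config.trend_temp_c_per_decade * elapsed_years / 10.0
    out = base.copy()
    out["tmin_c"] = base["tmin_c"] + warming
    out["tmax_c"] = base["tmax_c"] + warming
    out["precip_mm"] = base["precip_mm"] * config.trend_precip_multiplier
    return out


def simulate_water_levels(
    climate: pd.DataFrame,
    params: TrueParams,
    covariates: pd.DataFrame,
    init_level: float,
    seed: int,
    floor_mm: float | None = None,
    well_id: str = "synthetic-well",
) -> pd.DataFrame:
    """Simulate a daily water-level series from the autoregressive equation.

    ``covariates`` supplies the exogenous regressors (previous-day rain,
    7-day rain, PET, PET^2, SPEI) for each simulated day; the autoregressive
    term is propagated from the simulation itself, starting at ``init_level``
    (the level on the day before the first covariate row).  Gaussian noise
    with SD ``params.sigma`` is added each day (``sigma = 0`` gives the
    deterministic recursion).

    If ``floor_mm`` is given, levels are clipped from below, emulating a
    monitoring well of finite depth (the field wells end 1 m below ground).

    Returns a DataFrame (date, well_id, level_mm).
    """
    required = ["date", "precip_prev_mm", "pet_mm_day", "pet_sq", "weekprecip_mm", "spei_12"]
    missing = set(required).difference(covariates.columns)
    if missing:
        raise ValueError(f"covariates lack columns: {sorted(missing)}")
    cov_dates = pd.to_datetime(covariates["date"])
    clim_dates = pd.to_datetime(climate["date"])
    if not cov_dates.isin(clim_dates).all():
        raise ValueError("covariate dates are not aligned to climate dates")
    if len(cov_dates) > 1 and not (cov_dates.diff().iloc[1:] == pd.Timedelta(days=1)).all():
        raise ValueError("covariate dates must be contiguous daily values")

    precip = covariates["precip_prev_mm"].to_numpy(dtype=float)
    pet = covariates["pet_mm_day"].to_numpy(dtype=float)
    pet_sq = covariates["pet_sq"].to_numpy(dtype=float)
    week = covariates["weekprecip_mm"].to_numpy(dtype=float)
    spei = covariates["spei_12"].to_numpy(dtype=float)
    n = precip.size

    p = params
    # Per-day split of the linear predictor into an exogenous part and the
    # slope on the previous day's level (AR term appears in two interactions).
    exog = (
        p.alpha
        + p.beta_precip * precip
        + p.beta_pet * pet
        + p.beta_pet2 * pet_sq
        + p.beta_weekprecip * week
        + p.beta_spei * spei
        + p.beta_spei_precip * spei * precip
    )
    ar_slope = p.beta_ar + p.beta_precip_ar * precip + p.beta_spei_ar_precip * spei * precip

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, p.sigma, size=n)
    levels = np.empty(n)
    prev = float(init_level)
    for t in range(n):
        lvl = exog[t] + ar_slope[t] * prev + noise[t]
        if floor_mm is not None and lvl < floor_mm:
            lvl = floor_mm
        levels[t] = lvl
        prev = lvl

    return pd.DataFrame(
        {"date": cov_dates.to_numpy(), "well_id": well_id, "level_mm": levels}
    )


def neutral_scenario_config(config: ClimateGenConfig, seed: int) -> ClimateGenConfig:
    """A copy of ``config`` with trend knobs neutral and a new seed."""
    return replace(
        config, trend_temp_c_per_decade=0.0, trend_precip_multiplier=1.0, seed=seed
    )
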