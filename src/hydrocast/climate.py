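"""Climate covariates for ephemeral-wetland water-level modelling.

Turns raw daily climate (precipitation, air-temperature extremes) into the
regressors the autoregressive water-level model uses:

* daily potential evapotranspiration (PET) by the Hargreaves--Samani
  temperature method, with extraterrestrial radiation from standard solar
  geometry;
* monthly Hargreaves PET and the monthly climatic water balance D = P - PET;
* the standardized precipitation--evapotranspiration index (SPEI) at a
  k-month scale, via an unbiased-PWM L-moment fit of the three-parameter
  log-logistic distribution, per calendar month;
* lagged and rolling precipitation features (previous-day rain, 7-day rain
  sum, days since last rain).

All water depths are mm, temperatures degC, PET mm/day (daily) or mm/month
(monthly).  Daily tables are pandas DataFrames with a ``date`` column
(datetime64, contiguous daily); monthly series are indexed by a monthly
``PeriodIndex``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "extraterrestrial_radiation",
    "hargreaves_samani_daily_pet",
    "hargreaves_monthly_pet",
    "monthly_water_balance",
    "spei",
    "precip_features",
    "build_covariates",
    "SpeiFitError",
]

# Solar constant, MJ m-2 min-1 (FAO-56 convention)
_GSC = 0.0820
# Latent heat conversion: 1 mm evaporated water ~ 2.45 MJ m-2
_MJ_PER_MM = 2.45

#: Regressor columns of a covariate table (``days_since_rain`` is reported
#: for completeness but is not part of the water-level model).
REGRESSOR_COLUMNS = [
    "lag_level_mm",
    "precip_prev_mm",
    "pet_mm_day",
    "pet_sq",
    "weekprecip_mm",
    "spei_12",
]


def extraterrestrial_radiation(latitude_deg, day_of_year):
    """Daily extraterrestrial radiation Ra, as equivalent evaporation (mm/day).

    Standard solar geometry: inverse relative Earth--Sun distance, solar
    declination and sunset hour angle combined into the daily top-of-atmosphere
    radiation total, then converted from MJ m-2 day-1 to mm/day by dividing by
    the latent heat equivalent 2.45 MJ m-2 mm-1.

    Parameters
    ----------
    latitude_deg : float or array
        Geographic latitude, degrees north, in (-66.5, 66.5).  Latitudes with
        polar night/day are outside the scope of this application.
    day_of_year : int or array
        Julian day in [1, 366].
    """
    lat = np.asarray(latitude_deg, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(doy)):
        raise ValueError("latitude and day_of_year must be finite")
    if np.any(np.abs(lat) >= 66.5):
        raise ValueError(
            "latitudes with polar night (|lat| >= 66.5) are not supported"
        )
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day_of_year must lie in [1, 366]")

    phi = np.deg2rad(lat)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra_mj = (
        (24.0 * 60.0 / np.pi)
        * _GSC
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return ra_mj / _MJ_PER_MM


def hargreaves_samani_daily_pet(tmin_c, tmax_c, latitude_deg, day_of_year):
    """Daily Hargreaves--Samani potential evapotranspiration (mm/day).

    PET = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin), with Ra in
    equivalent mm/day and Tmean = (Tmax + Tmin) / 2.  Negative values (very
    cold air) are clipped to zero: the index is a demand, not a flux balance.
    """
    tmin = np.asarray(tmin_c, dtype=float)
    tmax = np.asarray(tmax_c, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax_c must be >= tmin_c for every day")
    ra = extraterrestrial_radiation(latitude_deg, day_of_year)
    tmean = 0.5 * (tmax + tmin)
    pet = 0.0023 * ra * (tmean + 17.8) * np.sqrt(tmax - tmin)
    return np.maximum(pet, 0.0)


def hargreaves_monthly_pet(monthly: pd.DataFrame, latitude_deg: float) -> pd.Series:
    """Monthly Hargreaves PET (mm/month) from monthly-mean temperature extremes.

    Parameters
    ----------
    monthly : DataFrame indexed by a monthly PeriodIndex with columns
        ``tmin_c`` and ``tmax_c`` (monthly means of the daily extremes).
    latitude_deg : site latitude, degrees north.

    The daily-equivalent Hargreaves--Samani value is computed with Ra at the
    mid-month day of year and scaled by the number of days in the month.
    """
    if not isinstance(monthly.index, pd.PeriodIndex) or monthly.index.freqstr[0] != "M":
        raise ValueError("monthly input must be indexed by a monthly PeriodIndex")
    missing = {"tmin_c", "tmax_c"}.difference(monthly.columns)
    if missing:
        raise ValueError(f"monthly input lacks columns: {sorted(missing)}")
    if monthly[["tmin_c", "tmax_c"]].isna().any().any():
        raise ValueError("missing months (NaN temperatures) in monthly input")
    mid = monthly.index.to_timestamp() + pd.Timedelta(days=14)
    doy = mid.dayofyear.to_numpy()
    days_in_month = monthly.index.days_in_month.to_numpy()
    pet_daily = hargreaves_samani_daily_pet(
        monthly["tmin_c"].to_numpy(), monthly["tmax_c"].to_numpy(), latitude_deg, doy
    )
    return pd.Series(pet_daily * days_in_month, index=monthly.index, name="pet_total_mm")


def monthly_water_balance(climate: pd.DataFrame, latitude_deg: float) -> pd.DataFrame:
    """Monthly climatic water balance D = P - PET from a daily climate table.

    Returns a DataFrame indexed by monthly period with columns
    ``precip_total_mm``, ``pet_total_mm`` and ``balance_mm``.  Monthly PET is
    the Hargreaves value computed from monthly-mean temperature extremes.
    """
    _check_daily(climate, ["precip_mm", "tmin_c", "tmax_c"])
    months = climate["date"].dt.to_period("M")
    precip = climate.groupby(months)["precip_mm"].sum()
    temps = climate.groupby(months)[["tmin_c", "tmax_c"]].mean()
    pet = hargreaves_monthly_pet(temps, latitude_deg)
    out = pd.DataFrame(
        {
            "precip_total_mm": precip,
            "pet_total_mm": pet,
            "balance_mm": precip - pet,
        }
    )
    out.index.name = "month"
    return out


class SpeiFitError(RuntimeError):
    """Raised when a log-logistic fit for SPEI is degenerate for some month."""


def _pwm_fit(x: np.ndarray):
    """Log-logistic parameters from the order-(0,1,2) unbiased PWMs
    ``w_s = E[X (1-F)^s]`` of an ascending-sorted sample:

        beta  = (2 w1 - w0) / (6 w1 - w0 - 6 w2)   (shape, = lam2 / lam3)
        alpha = (w0 - 2 w1) beta / g               (scale), g = G(1+1/b) G(1-1/b)
        gamma = w0 - alpha g                       (location)
    """
    n = x.size
    j = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = np.sum(x * (n - j)) / (n * (n - 1))
    w2 = np.sum(x * (n - j) * (n - j - 1)) / (n * (n - 1) * (n - 2))
    lam2 = w0 - 2.0 * w1
    lam3 = w0 - 6.0 * w1 + 6.0 * w2
    if lam3 <= 0:
        raise SpeiFitError("non-positive third L-moment")
    beta = lam2 / lam3
    if not np.isfinite(beta) or beta <= 1.0:
        raise SpeiFitError(
            f"log-logistic shape {beta!r} outside valid range (>1); "
            "balance sample too skewed or too short"
        )
    g = special.gamma(1.0 + 1.0 / beta) * special.gamma(1.0 - 1.0 / beta)
    alpha = lam2 * beta / g
    gamma = w0 - alpha * g
    if not (np.isfinite(alpha) and alpha > 0.0 and np.isfinite(gamma)):
        raise SpeiFitError("degenerate log-logistic scale/location")
    return beta, alpha, gamma


def _loglogistic_from_lmoments(x: np.ndarray):
    """Fit the 3-parameter log-logistic by unbiased-PWM L-moments.

    The log-logistic supports only positive L-skewness; when the sample's
    third L-moment is negative (possible by chance in near-symmetric balance
    series), the reflected sample -x is fitted instead and the CDF evaluated
    as F(x) = 1 - F_reflected(-x).  Returns ``(beta, alpha, gamma,
    reflected)``.

    Requires at least 4 distinct values; the shape must exceed 1 so the mean
    exists.  Degenerate windows raise :class:`SpeiFitError`.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 4:
        raise SpeiFitError(f"need at least 4 values to fit, got {n}")
    if np.ptp(x) == 0.0:
        raise SpeiFitError("constant balance values: log-logistic fit undefined")
    try:
        return (*_pwm_fit(x), False)
    except SpeiFitError as err:
        if "third L-moment" not in str(err):
            raise
    return (*_pwm_fit(np.sort(-x)), True)


def _loglogistic_cdf(x, beta, alpha, gamma, reflected=False):
    x = np.asarray(x, dtype=float)
    if reflected:
        return 1.0 - _loglogistic_cdf(-x, beta, alpha, gamma)
    z = x - gamma
    cdf = np.zeros_like(z)
    pos = z > 0
    cdf[pos] = 1.0 / (1.0 + (alpha / z[pos]) ** beta)
    # probabilities clipped away from {0,1} so the normal quantile is finite
    return np.clip(cdf, 1e-6, 1.0 - 1e-6)


def spei(
    balance: pd.DataFrame | pd.Series,
    scale: int = 12,
    calibration: tuple | None = None,
) -> pd.Series:
    """Standardized precipitation--evapotranspiration index at a k-month scale.

    For every month the trailing ``scale``-month sum of the climatic water
    balance D = P - PET is standardized against the fitted distribution of
    that calendar month's sums over the calibration years: a three-parameter
    log-logistic fitted by unbiased-PWM L-moments, mapped through its CDF and
    the standard-normal quantile function.  Negative values indicate drought.

    Parameters
    ----------
    balance : output of :func:`monthly_water_balance` (or a Series of
        ``balance_mm`` indexed by monthly period).
    scale : window length in months (default 12).  The first ``scale - 1``
        months of record are undefined (NaN).
    calibration : optional ``(start, end)`` pair of ``'YYYY-MM'`` strings or
        monthly Periods delimiting the fitting years; default is the whole
        series.  About 20+ years are needed for a stable fit.

    Returns
    -------
    Series of SPEI values indexed like the input; name ``spei_<scale>``.
    """
    if isinstance(balance, pd.DataFrame):
        series = balance["balance_mm"]
    else:
        series = balance
    if not isinstance(series.index, pd.PeriodIndex):
        raise ValueError("balance must be indexed by a monthly PeriodIndex")
    if scale < 1:
        raise ValueError("scale must be >= 1")
    idx = series.index
    if not idx.equals(pd.period_range(idx[0], periods=len(idx), freq="M")):
        raise ValueError("balance series has month gaps")

    rolling = series.rolling(scale).sum()
    out = pd.Series(np.nan, index=idx, name=f"spei_{scale}")

    if calibration is None:
        calib_mask = pd.Series(True, index=idx)
    else:
        lo, hi = (pd.Period(p, freq="M") for p in calibration)
        calib_mask = pd.Series((idx >= lo) & (idx <= hi), index=idx)

    for month in range(1, 13):
        sel = idx.month == month
        vals = rolling[sel]
        fit_vals = vals[calib_mask[sel] & vals.notna()]
        if fit_vals.empty:
            continue
        try:
            beta, alpha, gamma, refl = _loglogistic_from_lmoments(fit_vals.to_numpy())
        except SpeiFitError as err:
            raise SpeiFitError(f"calendar month {month}: {err}") from err
        ok = vals.notna()
        cdf = _loglogistic_cdf(vals[ok].to_numpy(), beta, alpha, gamma, refl)
        out.loc[vals.index[ok]] = stats.norm.ppf(cdf)
    return out


def precip_features(climate: pd.DataFrame) -> pd.DataFrame:
    """Lagged precipitation features for each day of a contiguous daily record.

    Returns a DataFrame aligned to ``climate['date']`` with

    * ``precip_prev_mm``  -- rain on the previous day (NaN on the first day);
    * ``weekprecip_mm``   -- rain summed over the previous seven days
      (t-7 ... t-1, excluding day t; NaN until seven prior days exist);
    * ``days_since_rain`` -- whole days since the last day with rain > 0,
      counting from t-1 (1 if it rained yesterday); +inf before the first
      rain event on record.
    """
    _check_daily(climate, ["precip_mm"])
    rain = climate["precip_mm"].to_numpy(dtype=float)
    if np.any(rain < 0):
        raise ValueError("negative precipitation")
    n = rain.size
    prev = np.concatenate([[np.nan], rain[:-1]])
    week = pd.Series(rain).rolling(7).sum().shift(1).to_numpy()

    idx = np.arange(n)
    last_wet = np.maximum.accumulate(np.where(rain > 0, idx, -1))
    last_wet_before = np.concatenate([[-1], last_wet[:-1]])
    dsr = np.where(last_wet_before >= 0, idx - last_wet_before, np.inf)

    return pd.DataFrame(
        {
            "date": climate["date"].to_numpy(),
            "precip_prev_mm": prev,
            "weekprecip_mm": week,
            "days_since_rain": dsr,
        }
    )


def build_covariates(
    levels: pd.DataFrame,
    climate: pd.DataFrame,
    latitude_deg: float,
    spei_monthly: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-day covariate table for the water-level model.

    One row per modelable day: the previous day's observed level (AR term),
    previous-day and 7-day precipitation, same-day PET and PET^2, and the
    SPEI of the day's own calendar month.  Rows where any regressor is
    undefined (record edges, missing SPEI months) are dropped; the count of
    dropped rows is stored in ``result.attrs['n_dropped']``.

    Parameters
    ----------
    levels : DataFrame with ``date`` and ``level_mm`` (one well, contiguous).
    climate : DataFrame with ``date``, ``precip_mm``, ``tmin_c``, ``tmax_c``
        covering at least the level record.
    latitude_deg : site latitude (degrees north) for PET.
    spei_monthly : SPEI series indexed by monthly period
        (see :func:`spei`).
    """
    _check_daily(levels, ["level_mm"])
    _check_daily(climate, ["precip_mm", "tmin_c", "tmax_c"])

    feats = precip_features(climate)
    doy = climate["date"].dt.dayofyear.to_numpy()
    pet = hargreaves_samani_daily_pet(
        climate["tmin_c"].to_numpy(), climate["tmax_c"].to_numpy(), latitude_deg, doy
    )
    clim = feats.assign(pet_mm_day=pet, pet_sq=pet**2)

    lag = levels["level_mm"].shift(1)
    table = levels[["date", "level_mm"]].assign(lag_level_mm=lag.to_numpy())
    table = table.merge(clim, on="date", how="left", validate="one_to_one")
    months = table["date"].dt.to_period("M")
    table["spei_12"] = spei_monthly.reindex(months).to_numpy()

    cols = ["date", "level_mm"] + REGRESSOR_COLUMNS + ["days_since_rain"]
    table = table[cols]
    defined = table[REGRESSOR_COLUMNS].notna().all(axis=1)
    n_dropped = int((~defined).sum())
    table = table.loc[defined].reset_index(drop=True)
    if table.empty:
        raise ValueError("no rows with a full set of covariates")
    table.attrs["n_dropped"] = n_dropped
    return table


def _check_daily(df: pd.DataFrame, cols: Sequence[str]) -> None:
    if "date" not in df.columns:
        raise ValueError("table must have a 'date' column")
    missing = set(cols).difference(df.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    dates = pd.to_datetime(df["date"])
    if len(dates) > 1:
        deltas = dates.diff().iloc[1:]
        if not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("dates must be contiguous daily values")
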