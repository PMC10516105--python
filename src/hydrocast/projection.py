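"""Forward simulation of daily water levels under climate scenarios.

For every retained posterior draw, the fitted autoregressive equation is run
recursively over a scenario climate table: the AR input of day t is the
PREDICTED level of day t-1 (unlike one-step validation, which uses observed
lags), and by default Gaussian process noise with the draw's own sigma^2 is
added each day (posterior-predictive simulation).  Covariates (PET, PET^2,
7-day rain, previous-day rain, SPEI-12) are recomputed from the scenario
climate exactly as for the observed record; the scenario must therefore
include at least 12 months of climate before the first projected day so the
SPEI window is defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import climate as _climate
from .model import COEF_NAMES, PosteriorDraws

__all__ = ["ScenarioEnsemble", "scenario_covariates", "project", "ensemble_summary"]


@dataclass
class ScenarioEnsemble:
    """Per-draw daily level trajectories under one climate scenario."""

    scenario_id: str
    well_id: str
    dates: pd.DatetimeIndex
    levels: np.ndarray  # (n_draws, n_days)
    draw_indices: np.ndarray

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 2 or self.levels.shape[1] != len(self.dates):
            raise ValueError("levels must be (n_draws x n_days)")

    @property
    def n_draws(self) -> int:
        return self.levels.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        n_d, n_t = self.levels.shape
        return pd.DataFrame(
            {
                "scenario": self.scenario_id,
                "well_id": self.well_id,
                "draw": np.repeat(self.draw_indices, n_t),
                "date": np.tile(self.dates.to_numpy(), n_d),
                "level_mm": self.levels.ravel(),
            }
        )

    def plot(self, ax=None, quantiles=(0.1, 0.5, 0.9)):
        """Quantile-band plot of the ensemble (simple per-well summary)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        bands = ensemble_summary(self, quantiles)
        ax.fill_between(
            self.dates, bands.iloc[:, 0], bands.iloc[:, -1], alpha=0.3,
            label=f"q{quantiles[0]:.2f}-q{quantiles[-1]:.2f}",
        )
        mid = bands.columns[len(quantiles) // 2]
        ax.plot(self.dates, bands[mid], lw=1.0, label=mid)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel("water level (mm)")
        ax.set_title(f"{self.well_id} under {self.scenario_id}")
        ax.legend(loc="upper right", fontsize="small")
        return ax


def scenario_covariates(
    scenario_climate: pd.DataFrame,
    latitude_deg: float,
    spei_calibration: tuple | None = None,
) -> pd.DataFrame:
    """Covariate table (without AR/level columns) from a scenario climate.

    SPEI-12 is calibrated on ``spei_calibration`` (a (start, end) month pair,
    e.g. a historical baseline included at the head of the table) or, when
    None, on the scenario period itself.  Rows whose exogenous covariates are
    undefined (the first week, the first 11 SPEI months) are dropped.
    """
    _climate._check_daily(scenario_climate, ["precip_mm", "tmin_c", "tmax_c"])
    balance = _climate.monthly_water_balance(scenario_climate, latitude_deg)
    spei_12 = _climate.spei(balance, scale=12, calibration=spei_calibration)
    feats = _climate.precip_features(scenario_climate)
    doy = scenario_climate["date"].dt.dayofyear.to_numpy()
    pet = _climate.hargreaves_samani_daily_pet(
        scenario_climate["tmin_c"].to_numpy(),
        scenario_climate["tmax_c"].to_numpy(),
        latitude_deg,
        doy,
    )
    table = feats.assign(pet_mm_day=pet, pet_sq=pet**2)
    months = table["date"].dt.to_period("M")
    table["spei_12"] = spei_12.reindex(months).to_numpy()
    exog = ["precip_prev_mm", "weekprecip_mm", "pet_mm_day", "pet_sq", "spei_12"]
    table = table.loc[table[exog].notna().all(axis=1)].reset_index(drop=True)
    if table.empty:
        raise ValueError(
            "scenario climate too short: no day has a defined SPEI-12 window "
            "(needs >= 12 months of spin-up climate)"
        )
    return table


def project(
    draws: PosteriorDraws,
    scenario_climate: pd.DataFrame,
    latitude_deg: float,
    init_level: float = 0.0,
    include_process_noise: bool = True,
    seed: int = 0,
    scenario_id: str = "scenario",
    well_id: str = "well",
    spei_calibration: tuple | None = None,
    draw_indices=None,
    start_date=None,
    floor_mm: float | None = None,
) -> ScenarioEnsemble:
    """Simulate per-draw daily level trajectories under a climate scenario.

    Parameters
    ----------
    draws : retained posterior draws of a fitted model.
    scenario_climate : daily (date, precip_mm, tmin_c, tmax_c) table covering
        at least 12 months before the first day to be reported.
    init_level : level (mm) on the day before the first simulated day;
        defaults to the ground surface (0 mm).  The early months double as
        spin-up: AR memory of the initial condition decays within months for
        beta_ar < 1.
    include_process_noise : add N(0, sigma^2_draw) innovations per day
        (posterior-predictive simulation, the default); when off, each draw's
        trajectory is the deterministic mean recursion.
    draw_indices : optional subset of draw rows to simulate (memory control
        for long horizons).
    start_date : optional first date to keep in the returned ensemble
        (simulation still starts at the first covariate-complete day).
    floor_mm : optional lower clip emulating finite well depth.
    """
    cov = scenario_covariates(scenario_climate, latitude_deg, spei_calibration)
    B = draws.coefficients
    if draw_indices is None:
        draw_indices = np.arange(B.shape[0])
    else:
        draw_indices = np.asarray(draw_indices)
    B = B[draw_indices]
    sigma = np.sqrt(draws.sigma2[draw_indices])

    names = {n: i for i, n in enumerate(COEF_NAMES)}
    pr = cov["precip_prev_mm"].to_numpy(dtype=float)
    sp = cov["spei_12"].to_numpy(dtype=float)
    exog_cols = np.column_stack(
        [
            np.ones_like(pr),
            pr,
            cov["pet_mm_day"].to_numpy(dtype=float),
            cov["pet_sq"].to_numpy(dtype=float),
            cov["weekprecip_mm"].to_numpy(dtype=float),
            sp,
            sp * pr,
        ]
    )
    exog_idx = [names[k] for k in
                ["alpha", "beta_precip", "beta_pet", "beta_pet2",
                 "beta_weekprecip", "beta_spei", "beta_spei_precip"]]
    c0 = B[:, exog_idx] @ exog_cols.T  # (draws, days)
    c1 = (
        B[:, [names["beta_ar"]]]
        + np.outer(B[:, names["beta_precip_ar"]], pr)
        + np.outer(B[:, names["beta_spei_ar_precip"]], sp * pr)
    )

    n_draws, n_days = c0.shape
    rng = np.random.default_rng(seed)
    levels = np.empty((n_draws, n_days))
    prev = np.full(n_draws, float(init_level))
    for t in range(n_days):
        cur = c0[:, t] + c1[:, t] * prev
        if include_process_noise:
            cur = cur + sigma * rng.standard_normal(n_draws)
        if floor_mm is not None:
            np.maximum(cur, floor_mm, out=cur)
        levels[:, t] = cur
        prev = cur

    dates = pd.DatetimeIndex(pd.to_datetime(cov["date"]))
    if start_date is not None:
        keep = dates >= pd.Timestamp(start_date)
        dates = dates[keep]
        levels = levels[:, keep]
        if levels.shape[1] == 0:
            raise ValueError("start_date is beyond the scenario climate")
    return ScenarioEnsemble(
        scenario_id=scenario_id,
        well_id=well_id,
        dates=dates,
        levels=levels,
        draw_indices=draw_indices,
    )


def ensemble_summary(ens: ScenarioEnsemble, quantiles=(0.05, 0.5, 0.95)) -> pd.DataFrame:
    """Per-day quantile bands across draws (monotone in quantile level)."""
    if ens.n_draws < 2:
        raise ValueError("need at least two draws to summarize an ensemble")
    q = np.asarray(quantiles, dtype=float)
    if q.size == 0 or np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie in (0, 1)")
    vals = np.quantile(ens.levels, q, axis=0)
    return pd.DataFrame(
        vals.T, index=ens.dates, columns=[f"q{x:g}" for x in q]
    )
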