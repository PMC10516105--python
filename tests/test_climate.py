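"""Covariate computations vs independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hydrocast as hc
from hydrocast.climate import SpeiFitError, _loglogistic_from_lmoments, _pwm_fit


def radiation_oracle(lat_deg, doy):
    """Independently coded daily top-of-atmosphere radiation (mm/day)."""
    import math

    phi = math.radians(lat_deg)
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    dec = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(dec))))
    ra = (
        24 * 60 / math.pi * 0.0820 * dr
        * (ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws))
    )
    return ra / 2.45


class TestExtraterrestrialRadiation:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        for lat, doy in zip(rng.uniform(-60, 60, 50), rng.integers(1, 366, 50)):
            assert hc.extraterrestrial_radiation(lat, int(doy)) == pytest.approx(
                radiation_oracle(lat, int(doy)), abs=1e-9
            )

    def test_equatorial_band(self):
        vals = [hc.extraterrestrial_radiation(0.0, d) for d in range(1, 366)]
        assert min(vals) > 13.0 and max(vals) < 15.5

    def test_northern_summer_exceeds_winter(self):
        assert hc.extraterrestrial_radiation(30.5, 172) > hc.extraterrestrial_radiation(30.5, 355)

    def test_hemispheric_symmetry(self):
        for doy in (15, 100, 200, 310):
            mirrored = int((doy + 182.5) % 365) or 365
            a = hc.extraterrestrial_radiation(35.0, doy)
            b = hc.extraterrestrial_radiation(-35.0, mirrored)
            # only approximate: the inverse Earth-Sun distance term is not
            # mirrored by a half-year shift (up to ~7% asymmetry)
            assert a == pytest.approx(b, rel=0.07)

    def test_polar_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hc.extraterrestrial_radiation(70.0, 100)
        with pytest.raises(ValueError):
            hc.extraterrestrial_radiation(30.0, 0)
        with pytest.raises(ValueError):
            hc.extraterrestrial_radiation(np.nan, 100)


class TestDailyPet:
    def test_zero_diurnal_range_gives_zero(self):
        assert hc.hargreaves_samani_daily_pet(20.0, 20.0, 30.5, 172) == 0.0

    def test_zero_temperature_factor(self):
        # Tmean = -17.8 cancels the temperature term
        assert hc.hargreaves_samani_daily_pet(-22.8, -12.8, 30.5, 15) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula(self):
        ra = radiation_oracle(30.5, 172)
        expected = 0.0023 * ra * ((33 + 22) / 2 + 17.8) * np.sqrt(33 - 22)
        got = hc.hargreaves_samani_daily_pet(22.0, 33.0, 30.5, 172)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_inverted_extremes_rejected(self):
        with pytest.raises(ValueError):
            hc.hargreaves_samani_daily_pet(25.0, 20.0, 30.5, 100)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(1)
        tmin = rng.uniform(-40, 30, 200)
        tmax = tmin + rng.uniform(0, 20, 200)
        doy = rng.integers(1, 366, 200)
        pet = hc.hargreaves_samani_daily_pet(tmin, tmax, 30.5, doy)
        assert np.all(pet >= 0)


class TestMonthlyPet:
    @staticmethod
    def _monthly(tmin, tmax, year=2001):
        idx = pd.period_range(f"{year}-01", periods=12, freq="M")
        return pd.DataFrame({"tmin_c": tmin, "tmax_c": tmax}, index=idx)

    def test_zero_diurnal_range_all_months_zero(self):
        pet = hc.hargreaves_monthly_pet(self._monthly([15.0] * 12, [15.0] * 12), 30.5)
        assert (pet == 0).all()

    def test_july_exceeds_january_for_identical_temperatures(self):
        pet = hc.hargreaves_monthly_pet(self._monthly([15.0] * 12, [25.0] * 12), 30.5)
        assert pet.iloc[6] > pet.iloc[0]

    def test_matches_oracle_sum(self):
        rng = np.random.default_rng(2)
        tmin = rng.uniform(0, 20, 12)
        tmax = tmin + rng.uniform(2, 15, 12)
        monthly = self._monthly(tmin, tmax)
        pet = hc.hargreaves_monthly_pet(monthly, 30.5)
        for i, period in enumerate(monthly.index):
            mid = period.to_timestamp() + pd.Timedelta(days=14)
            daily = 0.0023 * radiation_oracle(30.5, mid.dayofyear) * (
                (tmax[i] + tmin[i]) / 2 + 17.8
            ) * np.sqrt(tmax[i] - tmin[i])
            assert pet.iloc[i] == pytest.approx(max(daily, 0) * period.days_in_month, abs=1e-4)

    def test_missing_months_rejected(self):
        monthly = self._monthly([10.0] * 12, [20.0] * 12)
        monthly.loc[monthly.index[3], "tmin_c"] = np.nan
        with pytest.raises(ValueError):
            hc.hargreaves_monthly_pet(monthly, 30.5)


class TestSpei:
    @staticmethod
    def _balance_from(values, start="1981-01"):
        idx = pd.period_range(start, periods=len(values), freq="M")
        return pd.Series(np.asarray(values, dtype=float), index=idx, name="balance_mm")

    def test_standardization_property(self, climate_42yr):
        balance = hc.monthly_water_balance(climate_42yr, 30.5)
        s = hc.spei(balance, scale=12)
        for month in range(1, 13):
            vals = s[s.index.month == month].dropna()
            assert abs(vals.mean()) < 0.05
            assert abs(vals.std(ddof=0) - 1.0) < 0.1

    def test_first_window_undefined(self, climate_42yr):
        balance = hc.monthly_water_balance(climate_42yr, 30.5)
        s = hc.spei(balance, scale=12)
        assert s.iloc[:11].isna().all() and s.iloc[11:].notna().all()

    def test_monotone_in_balance(self):
        # larger rolling balance for a calendar month => larger SPEI
        rng = np.random.default_rng(4)
        raw = rng.normal(40, 25, 480)
        bal = self._balance_from(raw)
        s = hc.spei(bal, scale=12)
        roll = bal.rolling(12).sum()
        for month in (1, 6):
            sel = s.index.month == month
            order_roll = np.argsort(roll[sel].dropna().to_numpy())
            order_spei = np.argsort(s[sel].dropna().to_numpy())
            assert np.array_equal(order_roll, order_spei)

    def test_known_distribution_oracle(self):
        # balances drawn i.i.d. from a known log-logistic: the empirical SPEI
        # transform must approach the theoretical standardization
        # z = Phi^-1(F_true(x)) as the calibration sample grows
        beta, alpha, gamma = 8.0, 300.0, 500.0

        def err95(n_years, seed):
            rng = np.random.default_rng(seed)
            # scale=1 isolates the per-month fit: each value is one draw
            draws = stats.fisk.rvs(
                beta, loc=gamma, scale=alpha, size=n_years * 12, random_state=rng
            )
            s = hc.spei(self._balance_from(draws, start="0001-01"), scale=1)
            theory = stats.norm.ppf(stats.fisk.cdf(draws, beta, loc=gamma, scale=alpha))
            mid = np.abs(theory) < 2.0  # away from the extreme tails
            return np.quantile(np.abs(s.to_numpy()[mid] - theory[mid]), 0.95)

        # accuracy at a long calibration, and n^-1/2 style convergence
        assert err95(6400, seed=5) < 0.05
        assert err95(6400, seed=5) < err95(400, seed=5)

    def test_pwm_fit_recovers_known_parameters(self):
        beta, alpha, gamma = 6.0, 120.0, -40.0
        x = stats.fisk.rvs(beta, loc=gamma, scale=alpha, size=200_000,
                           random_state=np.random.default_rng(6))
        b, a, g, refl = _loglogistic_from_lmoments(x)
        assert not refl
        assert b == pytest.approx(beta, rel=0.05)
        assert a == pytest.approx(alpha, rel=0.05)
        assert g == pytest.approx(gamma, abs=0.05 * alpha)

    def test_year_permutation_invariance(self):
        # the fit is order independent: permuting years permutes SPEI values
        rng = np.random.default_rng(7)
        vals = rng.normal(30, 20, 30 * 12)
        bal = self._balance_from(vals)
        s1 = hc.spei(bal, scale=1)
        perm = rng.permutation(30)
        shuffled = vals.reshape(30, 12)[perm].ravel()
        s2 = hc.spei(self._balance_from(shuffled), scale=1)
        assert np.allclose(
            s1.to_numpy().reshape(30, 12)[perm], s2.to_numpy().reshape(30, 12)
        )

    def test_degenerate_window_reported(self):
        with pytest.raises(SpeiFitError):
            hc.spei(self._balance_from([5.0] * 240), scale=1)

    def test_calibration_window_controls_fit(self):
        rng = np.random.default_rng(8)
        bal = self._balance_from(rng.normal(0, 10, 600))
        full = hc.spei(bal, scale=12)
        early = hc.spei(bal, scale=12, calibration=("1981-01", "2000-12"))
        assert not np.allclose(full.dropna(), early.dropna())


class TestPrecipFeatures:
    @staticmethod
    def _table(rain):
        dates = pd.date_range("2020-01-01", periods=len(rain), freq="D")
        return pd.DataFrame({"date": dates, "precip_mm": rain})

    def test_window_arithmetic_example(self):
        rain = [10.0] + [0.0] * 11
        f = hc.precip_features(self._table(rain))
        # weekprecip spans t-7..t-1: days 1..7 (0-based) see the day-0 rain
        assert np.isnan(f["weekprecip_mm"].iloc[:7]).all()
        assert f["weekprecip_mm"].iloc[7] == 10.0
        assert (f["weekprecip_mm"].iloc[8:] == 0.0).all()
        assert f["precip_prev_mm"].iloc[1] == 10.0

    def test_all_dry_sentinel(self):
        f = hc.precip_features(self._table([0.0] * 30))
        assert np.isinf(f["days_since_rain"]).all()

    def test_brute_force_window_oracle(self):
        rng = np.random.default_rng(9)
        rain = np.where(rng.random(400) < 0.3, rng.gamma(0.8, 15, 400), 0.0)
        f = hc.precip_features(self._table(rain))
        for t in range(8, 400, 13):
            assert f["weekprecip_mm"].iloc[t] == pytest.approx(rain[t - 7 : t].sum())
            assert f["precip_prev_mm"].iloc[t] == rain[t - 1]
            wet_before = np.flatnonzero(rain[:t] > 0)
            expected = t - wet_before[-1] if wet_before.size else np.inf
            assert f["days_since_rain"].iloc[t] == expected

    def test_gapped_dates_rejected(self):
        tbl = self._table([1.0] * 10)
        with pytest.raises(ValueError):
            hc.precip_features(pd.concat([tbl.iloc[:5], tbl.iloc[6:]]))


class TestBuildCovariates:
    def test_single_lag_loss_and_row_values(self, climate_42yr, spei_12):
        dates = pd.date_range("2016-03-01", periods=40, freq="D")
        levels = pd.DataFrame(
            {"date": dates, "level_mm": np.linspace(-50, 70, 40)}
        )
        cov = hc.build_covariates(levels, climate_42yr, 30.5, spei_12)
        assert len(cov) == 39  # first day has no lag
        assert cov.attrs["n_dropped"] == 1
        # spot-check one row against hand-assembled values
        row = cov.iloc[10]
        day = row["date"]
        assert row["lag_level_mm"] == pytest.approx(
            float(levels.loc[levels["date"] == day - pd.Timedelta(days=1), "level_mm"].iloc[0])
        )
        clim = climate_42yr.set_index("date")
        assert row["precip_prev_mm"] == pytest.approx(
            clim.loc[day - pd.Timedelta(days=1), "precip_mm"]
        )
        week = clim.loc[day - pd.Timedelta(days=7) : day - pd.Timedelta(days=1), "precip_mm"].sum()
        assert row["weekprecip_mm"] == pytest.approx(week)
        assert row["pet_sq"] == pytest.approx(row["pet_mm_day"] ** 2)
        assert row["spei_12"] == pytest.approx(spei_12[pd.Period(day, freq="M")])

    def test_weekprecip_dominates_daily(self, covariates):
        assert (covariates["weekprecip_mm"] >= covariates["precip_prev_mm"] - 1e-9).all()

    def test_empty_output_rejected(self, climate_42yr, spei_12):
        levels = pd.DataFrame(
            {"date": pd.date_range("2016-03-01", periods=1), "level_mm": [0.0]}
        )
        with pytest.raises(ValueError):
            hc.build_covariates(levels, climate_42yr, 30.5, spei_12)
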