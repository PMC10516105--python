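"""Shared fixtures: one synthetic wetland, generated once per session.

The study conditions follow the package defaults: a 42-year synthetic
climate (1981-2022 style) at 30.5 degN, a monitoring record starting 2015,
and water levels generated from the autoregressive equation with the default
``TrueParams`` (sigma = 20 mm).  Model fits in tests use a reduced MCMC
(3 chains x 20,000 iterations, 2,000 burn-in, thinning 9 -> 6,000 retained
draws) and a variance prior wide enough to contain sigma^2 = 400.
"""

import numpy as np
import pandas as pd
import pytest

import hydrocast as hc
from hydrocast.projection import scenario_covariates

LATITUDE = 30.5
N_FIT_ROWS = 1500

#: reduced MCMC used throughout the test suite
TEST_MCMC = dict(n_chains=3, n_iterations=20_000, n_burnin=2_000, thin=9)
#: variance prior wide enough to contain the generating sigma^2
WIDE_PRIOR = hc.PriorSpec(variance_prior_hi=10_000.0)


def make_exog_covariates(climate: pd.DataFrame, latitude: float = LATITUDE) -> pd.DataFrame:
    """Exogenous covariate rows (no AR column) from a climate table."""
    return scenario_covariates(climate, latitude)


def simulate_well(
    climate: pd.DataFrame,
    params: hc.TrueParams,
    seed: int,
    start: str = "2015-01-01",
    latitude: float = LATITUDE,
) -> pd.DataFrame:
    """Water-level record simulated from the generating equation."""
    exog = make_exog_covariates(climate, latitude)
    exog = exog.loc[exog["date"] >= pd.Timestamp(start)].reset_index(drop=True)
    return hc.simulate_water_levels(climate, params, exog, init_level=0.0, seed=seed)


@pytest.fixture(scope="session")
def climate_42yr() -> pd.DataFrame:
    return hc.generate_climate(hc.ClimateGenConfig(seed=42))


@pytest.fixture(scope="session")
def spei_12(climate_42yr) -> pd.Series:
    balance = hc.monthly_water_balance(climate_42yr, LATITUDE)
    return hc.spei(balance, scale=12)


@pytest.fixture(scope="session")
def true_params() -> hc.TrueParams:
    return hc.TrueParams()


@pytest.fixture(scope="session")
def well_levels(climate_42yr, true_params) -> pd.DataFrame:
    return simulate_well(climate_42yr, true_params, seed=7)


@pytest.fixture(scope="session")
def covariates(climate_42yr, spei_12, well_levels) -> pd.DataFrame:
    """Model covariate table (with level_mm) for the synthetic well."""
    cov = hc.build_covariates(
        well_levels[["date", "level_mm"]], climate_42yr, LATITUDE, spei_12
    )
    return cov.iloc[:N_FIT_ROWS].reset_index(drop=True)


@pytest.fixture(scope="session")
def fitted(covariates) -> hc.WetlandLevelResults:
    mcmc = hc.McmcConfig(seed=3, **TEST_MCMC)
    return hc.fit_model(covariates, priors=WIDE_PRIOR, mcmc=mcmc)
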