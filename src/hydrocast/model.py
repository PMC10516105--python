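"""Bayesian first-order autoregressive water-level model.

One model per wetland: the daily water level is a linear function of the
previous day's level (AR term), previous-day rain, PET and PET^2, 7-day rain,
12-month SPEI, and three interactions (Precip:AR, SPEI:Precip,
SPEI:AR:Precip), with Gaussian errors:

    level_t = a + b_AR * level_{t-1} + b_P * P_{t-1} + b_PET * PET_t
              + b_PET2 * PET_t^2 + b_WP * WP_t + b_S * S_t
              + b_PA * P_{t-1} * level_{t-1} + b_SP * S_t * P_{t-1}
              + b_SPA * S_t * P_{t-1} * level_{t-1} + e_t,
    e_t ~ N(0, sigma^2).

Priors: every coefficient N(0, 100); sigma^2 ~ Uniform(0, 100).  Because the
likelihood is linear-Gaussian, the posterior is sampled by an exact two-block
Gibbs scheme: beta | sigma^2 is the conjugate multivariate-normal update, and
sigma^2 | beta is an inverse-gamma-shaped conditional truncated to the prior
support.  No generic MCMC machinery (and hence no adaptation) is needed; an
``n_adapt`` setting is accepted for config compatibility and ignored.

Usage follows the Model/Results convention::

    model = WetlandLevelModel.from_covariates(covariates, levels)
    res = model.fit(mcmc=McmcConfig(n_iterations=20_000, n_burnin=2_000, thin=10))
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "WetlandLevelModel",
    "WetlandLevelResults",
    "fit_model",
    "design_matrix",
    "gelman_rubin",
    "bayesian_p_value",
    "hpd_interval",
    "PARAM_NAMES",
    "COEF_NAMES",
]

COEF_NAMES = [
    "alpha",
    "beta_ar",
    "beta_precip",
    "beta_pet",
    "beta_pet2",
    "beta_weekprecip",
    "beta_spei",
    "beta_precip_ar",
    "beta_spei_precip",
    "beta_spei_ar_precip",
]
PARAM_NAMES = COEF_NAMES + ["sigma2"]


def design_matrix(table: pd.DataFrame) -> np.ndarray:
    """Build the (n x 10) design matrix from a covariate table.

    Columns follow ``COEF_NAMES``: intercept, AR term, previous-day rain,
    PET, PET^2, 7-day rain, SPEI, and the three interaction products.
    """
    required = ["lag_level_mm", "precip_prev_mm", "pet_mm_day", "pet_sq",
                "weekprecip_mm", "spei_12"]
    missing = set(required).difference(table.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    ar = table["lag_level_mm"].to_numpy(dtype=float)
    pr = table["precip_prev_mm"].to_numpy(dtype=float)
    pet = table["pet_mm_day"].to_numpy(dtype=float)
    pet2 = table["pet_sq"].to_numpy(dtype=float)
    wp = table["weekprecip_mm"].to_numpy(dtype=float)
    sp = table["spei_12"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones_like(ar), ar, pr, pet, pet2, wp, sp, pr * ar, sp * pr, sp * pr * ar]
    )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in covariate table")
    return X


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors: N(beta_mean, beta_variance) coefficients and a uniform
    prior on the error VARIANCE over (variance_prior_lo, variance_prior_hi)."""

    beta_mean: float = 0.0
    beta_variance: float = 100.0
    variance_prior_lo: float = 0.0
    variance_prior_hi: float = 100.0

    def __post_init__(self):
        if self.beta_variance <= 0:
            raise ValueError("beta_variance must be positive")
        if not 0 <= self.variance_prior_lo < self.variance_prior_hi:
            raise ValueError("need 0 <= variance_prior_lo < variance_prior_hi")


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run configuration (defaults: 3 chains of 400,000 iterations,
    300,000 burn-in, thinning 100)."""

    n_chains: int = 3
    n_iterations: int = 400_000
    thin: int = 100
    n_adapt: int = 1_000
    n_burnin: int = 300_000
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Retained posterior samples: a (draws x 11) array over ``PARAM_NAMES``
    (10 coefficients + sigma^2) with a chain id per row."""

    values: np.ndarray
    chain: np.ndarray
    param_names: list = field(default_factory=lambda: list(PARAM_NAMES))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.chain = np.asarray(self.chain, dtype=int)
        if self.values.ndim != 2 or self.values.shape[0] != self.chain.size:
            raise ValueError("values must be (n_draws x n_params) matching chain ids")
        if self.values.shape[1] != len(self.param_names):
            raise ValueError("column count does not match parameter names")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    @property
    def coefficients(self) -> np.ndarray:
        """(draws x 10) coefficient block, without sigma^2."""
        return self.values[:, :-1]

    @property
    def sigma2(self) -> np.ndarray:
        return self.values[:, -1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.param_names)
        df.insert(0, "chain", self.chain)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PosteriorDraws":
        names = [c for c in df.columns if c != "chain"]
        return cls(df[names].to_numpy(), df["chain"].to_numpy(), names)


class WetlandLevelModel:
    """Per-wetland Bayesian AR(1) fixed-effect water-level model.

    Parameters
    ----------
    endog : observed daily water levels (mm), one value per covariate row.
    exog : covariate table (see :func:`hydrocast.climate.build_covariates`)
        or a prebuilt (n x 10) design matrix.
    dates : optional per-row dates, kept for reporting.
    center : if True, non-constant design columns are mean-centered for
        numerical conditioning; draws are mapped back to the original
        parameterization, so results are expressed on the raw scale either
        way.  Off by default.
    """

    def __init__(self, endog, exog, dates=None, center: bool = False):
        y = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            X = design_matrix(exog)
            if dates is None and "date" in exog.columns:
                dates = pd.to_datetime(exog["date"]).to_numpy()
        else:
            X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("endog and exog have mismatched shapes")
        if y.size < 100:
            raise ValueError(
                f"need at least 100 aligned rows to fit, got {y.size}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite water levels")
        self._check_rank(X)
        self.endog = y
        self.exog = X
        self.dates = dates
        self.center = bool(center)
        self.exog_names = list(COEF_NAMES[: X.shape[1]]) if X.shape[1] == len(
            COEF_NAMES
        ) else [f"x{j}" for j in range(X.shape[1])]

    @classmethod
    def from_covariates(
        cls,
        covariates: pd.DataFrame,
        levels: pd.DataFrame | None = None,
        center: bool = False,
    ) -> "WetlandLevelModel":
        """Build the model from a covariate table, merging levels by date.

        If ``covariates`` already carries a ``level_mm`` column (as the
        covariate builder emits), ``levels`` may be omitted.
        """
        table = covariates
        if levels is not None:
            lv = levels[["date", "level_mm"]].rename(columns={"level_mm": "_y"})
            table = covariates.merge(lv, on="date", how="inner", validate="one_to_one")
            y = table["_y"].to_numpy(dtype=float)
        elif "level_mm" in covariates.columns:
            y = covariates["level_mm"].to_numpy(dtype=float)
        else:
            raise ValueError("levels not given and covariates carry no level_mm")
        return cls(y, table, center=center)

    @staticmethod
    def _check_rank(X: np.ndarray) -> None:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        deficient = piv[diag <= tol]
        if deficient.size:
            cols = [COEF_NAMES[j] if j < len(COEF_NAMES) else str(j) for j in deficient]
            raise ValueError(f"design matrix is rank deficient in columns: {cols}")

    def fit(
        self,
        priors: PriorSpec | None = None,
        mcmc: McmcConfig | None = None,
    ) -> "WetlandLevelResults":
        """Run the Gibbs sampler and return a results object."""
        priors = priors or PriorSpec()
        mcmc = mcmc or McmcConfig()
        if mcmc.n_adapt:
            logger.info(
                "n_adapt=%d has no effect: the exact Gibbs sampler needs no "
                "adaptation phase", mcmc.n_adapt,
            )

        X = self.exog
        shift = np.zeros(X.shape[1])
        if self.center:
            shift[1:] = X[:, 1:].mean(axis=0)
            X = X - shift  # constant column untouched (shift[0] = 0)

        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        keep = mcmc.n_retained_per_chain
        all_vals = []
        all_chain = []
        for c, ss in enumerate(seeds):
            vals = _gibbs_chain(self.endog, X, priors, mcmc, np.random.default_rng(ss))
            all_vals.append(vals)
            all_chain.append(np.full(keep, c))
        values = np.vstack(all_vals)
        if self.center:
            # alpha on the raw scale: a = a_c - sum_j m_j b_j
            values[:, 0] -= values[:, 1:-1] @ shift[1:]
        draws = PosteriorDraws(
            values, np.concatenate(all_chain), self.exog_names + ["sigma2"]
        )
        return WetlandLevelResults(self, draws, priors, mcmc)


def _gibbs_chain(y, X, priors, mcmc, rng):
    """One chain of the two-block Gibbs sampler.

    beta | sigma^2 ~ N(m, V) with V = (X'X/s2 + I/v0)^(-1), m = V X'y / s2
    (prior mean zero); sigma^2 | beta is inverse-gamma-shaped with shape
    n/2 - 1 and scale SSE/2, truncated to the uniform prior's support, drawn
    by rejection from the untruncated law with an inverse-CDF fallback.
    """
    n, p = X.shape
    v0 = priors.beta_variance
    m0 = priors.beta_mean
    lo, hi = priors.variance_prior_lo, priors.variance_prior_hi

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    lam, Q = linalg.eigh(XtX)
    lam = np.maximum(lam, 0.0)
    qty = Q.T @ Xty
    qm0 = Q.T @ np.full(p, m0)
    a_shape = 0.5 * n - 1.0
    if a_shape <= 0:
        raise ValueError("too few observations for the variance conditional")

    keep = mcmc.n_retained_per_chain
    out = np.empty((keep, p + 1))
    k = 0

    sigma2 = rng.uniform(lo if lo > 0 else min(hi, 1e-3), hi)  # overdispersed start
    for it in range(mcmc.n_iterations):
        # ---- beta | sigma2
        d = lam / sigma2 + 1.0 / v0
        w_mean = (qty / sigma2 + qm0 / v0) / d
        w = w_mean + rng.standard_normal(p) / np.sqrt(d)
        # ---- sigma2 | beta  (SSE via the eigenbasis)
        sse = yty - 2.0 * (w @ qty) + np.sum(lam * w * w)
        sse = max(sse, 1e-300)
        b_scale = 0.5 * sse
        sigma2 = _sample_trunc_invgamma(a_shape, b_scale, lo, hi, rng)
        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0 and k < keep:
            out[k, :p] = Q @ w
            out[k, p] = sigma2
            k += 1
    return out[:k]


def _sample_trunc_invgamma(a, b, lo, hi, rng, max_reject=100):
    """Sample sigma^2 from InvGamma(a, b) truncated to (lo, hi]."""
    z_hi = np.inf if lo <= 0 else 1.0 / lo
    z_lo = 1.0 / hi
    for _ in range(max_reject):
        z = rng.gamma(a, 1.0 / b)
        if z_lo < z < z_hi:
            return 1.0 / z
    # Rejection keeps failing: the posterior mass inside the prior support is
    # tiny; fall back to the inverse CDF on the truncated region.
    c_lo = stats.invgamma.cdf(lo, a, scale=b) if lo > 0 else 0.0
    c_hi = stats.invgamma.cdf(hi, a, scale=b)
    if not np.isfinite(c_hi) or c_hi - c_lo <= 1e-12:
        raise RuntimeError(
            "truncation region of the variance conditional has ~zero posterior "
            f"mass (P[sigma^2 <= {hi}] = {c_hi:.3g}); residual variance far "
            "exceeds the uniform prior's upper bound"
        )
    u = rng.uniform(c_lo, c_hi)
    return float(stats.invgamma.ppf(u, a, scale=b))


def fit_model(
    covariates: pd.DataFrame,
    levels: pd.DataFrame | None = None,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    center: bool = False,
) -> "WetlandLevelResults":
    """Convenience wrapper: build the model from tables and fit it."""
    return WetlandLevelModel.from_covariates(covariates, levels, center=center).fit(
        priors=priors, mcmc=mcmc
    )


def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Classic Gelman--Rubin potential scale reduction factor per parameter.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the chain means; values near 1 indicate
    convergence.  Requires >= 2 chains with >= 10 draws each.
    """
    chains = np.unique(draws.chain)
    if chains.size < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    per_chain = [draws.values[draws.chain == c] for c in chains]
    n = min(arr.shape[0] for arr in per_chain)
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    stacked = np.stack([arr[:n] for arr in per_chain])  # (m, n, p)
    within = stacked.var(axis=1, ddof=1).mean(axis=0)
    means = stacked.mean(axis=1)
    b_over_n = means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * within + b_over_n) / within)
    rhat = np.where((within == 0) & (b_over_n == 0), 1.0, rhat)
    return pd.Series(rhat, index=draws.param_names, name="rhat")


def bayesian_p_value(
    draws: PosteriorDraws,
    exog,
    endog,
    seed: int = 0,
    batch: int = 500,
) -> float:
    """Posterior predictive check with a chi-square-type discrepancy.

    For each retained draw, replicate data are simulated from the fitted
    Gaussian likelihood and the sum of squared standardized residuals is
    compared between replicate and observation; the Bayesian p-value is the
    fraction of draws whose replicate discrepancy is at least the observed
    one.  Values near 0.5 indicate the model reproduces its own data; values
    near 0 or 1 indicate misfit.
    """
    X = design_matrix(exog) if isinstance(exog, pd.DataFrame) else np.asarray(exog, float)
    y = np.asarray(endog, dtype=float)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for start in range(0, draws.n_draws, batch):
        B = draws.coefficients[start : start + batch]
        s = np.sqrt(draws.sigma2[start : start + batch])
        mu = X @ B.T  # (n, d)
        obs = ((y[:, None] - mu) / s) ** 2
        t_obs = obs.sum(axis=0)
        z = rng.standard_normal(mu.shape)
        t_rep = (z**2).sum(axis=0)
        n_ge += int(np.sum(t_rep >= t_obs))
    return n_ge / draws.n_draws


def hpd_interval(samples, mass: float = 0.95) -> tuple:
    """Narrowest interval containing ``mass`` of the (unimodal) sample.

    Computed from the sorted sample as the shortest window containing
    ceil(mass * n) points.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 2:
        raise ValueError("need at least two samples")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    widths = s[k - 1 :] - s[: n - k + 1]
    j = int(np.argmin(widths))
    return float(s[j]), float(s[j + k - 1])


class WetlandLevelResults:
    """Posterior results of a fitted wetland water-level model.

    Carries the retained draws and exposes the diagnostics used to judge a
    fit: Gelman--Rubin R-hat, the posterior predictive Bayesian p-value, 95%
    HPD intervals and the excludes-zero significance flag, plus one-step
    posterior-mean predictions.
    """

    def __init__(self, model, draws: PosteriorDraws, priors, mcmc):
        self.model = model
        self.draws = draws
        self.priors = priors
        self.mcmc = mcmc

    @property
    def param_names(self):
        return self.draws.param_names

    @cached_property
    def posterior_mean(self) -> pd.Series:
        return pd.Series(self.draws.values.mean(axis=0), index=self.param_names)

    @cached_property
    def posterior_median(self) -> pd.Series:
        return pd.Series(np.median(self.draws.values, axis=0), index=self.param_names)

    @cached_property
    def posterior_sd(self) -> pd.Series:
        return pd.Series(self.draws.values.std(axis=0, ddof=1), index=self.param_names)

    @cached_property
    def rhat(self) -> pd.Series:
        return gelman_rubin(self.draws)

    def bayesian_p_value(self, seed: int = 0) -> float:
        return bayesian_p_value(self.draws, self.model.exog, self.model.endog, seed=seed)

    def hpd(self, mass: float = 0.95) -> pd.DataFrame:
        rows = [hpd_interval(self.draws.values[:, j], mass)
                for j in range(len(self.param_names))]
        return pd.DataFrame(rows, index=self.param_names, columns=["lower", "upper"])

    def significant(self, mass: float = 0.95) -> pd.Series:
        """True where the HPD interval excludes zero (fixed effects only)."""
        coef = [n for n in self.param_names if n != "sigma2"]
        h = self.hpd(mass).loc[coef]
        return (h["lower"] > 0) | (h["upper"] < 0)

    def predict(self, covariates: pd.DataFrame | np.ndarray, draw_indices=None) -> np.ndarray:
        """One-step posterior predictions: (n_draws x n_days) mean levels,
        using the table's own (observed) lagged level as the AR input."""
        X = (
            design_matrix(covariates)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        B = self.draws.coefficients
        if draw_indices is not None:
            B = B[np.asarray(draw_indices)]
        return B @ X.T

    def diagnostics(self, seed: int = 0) -> pd.DataFrame:
        """Per-parameter summary: median, 95% HPD, R-hat, significance."""
        h = self.hpd(0.95)
        sig = self.significant(0.95)
        return pd.DataFrame(
            {
                "median": self.posterior_median,
                "hpd_lower": h["lower"],
                "hpd_upper": h["upper"],
                "rhat": self.rhat,
                "significant": sig.reindex(self.param_names),
            }
        )

    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            "Wetland water-level model (Bayesian AR(1), Gibbs sampler)",
            f"  observations: {self.model.endog.size}"
            f"   retained draws: {self.draws.n_draws}"
            f" ({self.mcmc.n_chains} chains)",
            "",
            f"{'parameter':<20}{'median':>12}{'hpd 2.5%':>12}{'hpd 97.5%':>12}"
            f"{'rhat':>8}  sig",
        ]
        for name, row in d.iterrows():
            sig = ""
            if row["significant"] is True:
                sig = "*"
            elif name == "sigma2":
                sig = "-"
            lines.append(
                f"{name:<20}{row['median']:>12.4f}{row['hpd_lower']:>12.4f}"
                f"{row['hpd_upper']:>12.4f}{row['rhat']:>8.3f}  {sig}"
            )
        lines.append("")
        lines.append("* 95% HPD excludes zero")
        return "\n".join(lines)
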