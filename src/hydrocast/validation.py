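"""Train/test validation of fitted water-level models.

The protocol splits the record into one consecutive training block of 75% of
the rows, starting at a random position within the first 25% of the record
(so the test set is the complement, possibly two blocks).  Accuracy is
reported per posterior draw on two surfaces:

* NRMSE -- root mean squared error of the one-step mean prediction divided by
  the range of measured water levels in the basin;
* wet/dry classification -- the proportion of days whose surface-water status
  (level > 0 mm) is predicted correctly, plus the two directional error
  rates (predicted dry while flooded, predicted flooded while dry).

One-step prediction feeds the OBSERVED previous-day level into the AR term by
default, which keeps per-day accuracy well defined on a test block that
precedes the training block in time; a free-running mode (recursing on the
model's own predictions within the test block) is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import COEF_NAMES, PosteriorDraws, WetlandLevelResults, design_matrix, hpd_interval

__all__ = [
    "SplitSpec",
    "ValidationReport",
    "split_train_test",
    "predict_one_step",
    "predict_free_running",
    "nrmse",
    "wet_dry_accuracy",
    "validate",
]


@dataclass(frozen=True)
class SplitSpec:
    """Consecutive-block split: ``train_fraction`` of the rows starting at
    ``start_index`` (drawn uniformly from the first 25% of rows when None)."""

    train_fraction: float = 0.75
    start_index: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_train_test(table: pd.DataFrame, spec: SplitSpec | None = None):
    """Partition rows into a consecutive training block and its complement.

    Returns ``(train, test)`` DataFrames preserving the original row order;
    together they contain every row exactly once.  The test set may consist
    of two blocks (before and after the training block).
    """
    spec = spec or SplitSpec()
    n = len(table)
    if n < 8:
        raise ValueError(f"record too short to split ({n} rows)")
    n_train = int(np.floor(spec.train_fraction * n))
    # the training block starts within the first (1 - f) share of the record
    max_start = int(np.floor((1.0 - spec.train_fraction) * n))
    if spec.start_index is None:
        start = int(np.random.default_rng(spec.seed).integers(0, max_start + 1))
    else:
        start = int(spec.start_index)
        if not 0 <= start <= max_start:
            raise ValueError(f"start_index must lie in [0, {max_start}]")
    train_mask = np.zeros(n, dtype=bool)
    train_mask[start : start + n_train] = True
    train = table.iloc[train_mask].reset_index(drop=True)
    test = table.iloc[~train_mask].reset_index(drop=True)
    return train, test


def predict_one_step(draws: PosteriorDraws, rows: pd.DataFrame) -> np.ndarray:
    """Per-draw deterministic mean predictions using observed lagged levels.

    Returns an (n_draws x n_days) matrix of predicted levels (mm).
    """
    X = design_matrix(rows)
    return draws.coefficients @ X.T


def predict_free_running(draws: PosteriorDraws, rows: pd.DataFrame, init_level: float) -> np.ndarray:
    """Per-draw mean predictions recursing on the model's own output.

    The AR term (and its interactions) uses the previous PREDICTED level
    instead of the observed one; ``init_level`` seeds the recursion.  Rows
    must be consecutive days.
    """
    B = draws.coefficients
    names = {n: i for i, n in enumerate(COEF_NAMES)}
    pr = rows["precip_prev_mm"].to_numpy(dtype=float)
    pet = rows["pet_mm_day"].to_numpy(dtype=float)
    pet2 = rows["pet_sq"].to_numpy(dtype=float)
    wp = rows["weekprecip_mm"].to_numpy(dtype=float)
    sp = rows["spei_12"].to_numpy(dtype=float)
    exog_cols = np.column_stack([np.ones_like(pr), pr, pet, pet2, wp, sp, sp * pr])
    exog_idx = [names[k] for k in
                ["alpha", "beta_precip", "beta_pet", "beta_pet2",
                 "beta_weekprecip", "beta_spei", "beta_spei_precip"]]
    c0 = B[:, exog_idx] @ exog_cols.T  # (draws, days)
    c1 = (
        B[:, [names["beta_ar"]]]
        + np.outer(B[:, names["beta_precip_ar"]], pr)
        + np.outer(B[:, names["beta_spei_ar_precip"]], sp * pr)
    )
    out = np.empty_like(c0)
    prev = np.full(B.shape[0], float(init_level))
    for t in range(c0.shape[1]):
        prev = c0[:, t] + c1[:, t] * prev
        out[:, t] = prev
    return out


def nrmse(observed, predicted, normalization_range: float) -> np.ndarray:
    """NRMSE per draw: RMSE of each prediction row divided by the basin's
    measured water-level range."""
    y = np.asarray(observed, dtype=float)
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    if p.shape[1] != y.size:
        raise ValueError("observed and predicted lengths differ")
    if not normalization_range > 0:
        raise ValueError("normalization range must be positive")
    rmse = np.sqrt(np.mean((p - y[None, :]) ** 2, axis=1))
    return rmse / normalization_range


def wet_dry_accuracy(observed, predicted):
    """Surface-water classification accuracy per draw.

    A day is flooded iff its level is strictly above the ground surface
    (> 0 mm).  Returns ``(proportion_correct, pct_dry_when_flooded,
    pct_flooded_when_dry)``, each an array over draws; the error percentages
    are fractions of ALL days (x100), as misclassification rates of the
    record, not conditional rates.
    """
    y = np.asarray(observed, dtype=float)
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    if y.size == 0:
        raise ValueError("empty input")
    if p.shape[1] != y.size:
        raise ValueError("observed and predicted lengths differ")
    obs_wet = y > 0
    pred_wet = p > 0
    correct = (pred_wet == obs_wet[None, :]).mean(axis=1)
    dry_when_flooded = (~pred_wet & obs_wet[None, :]).mean(axis=1) * 100.0
    flooded_when_dry = (pred_wet & ~obs_wet[None, :]).mean(axis=1) * 100.0
    return correct, dry_when_flooded, flooded_when_dry


@dataclass
class ValidationReport:
    """Per-draw accuracy distributions for one well's fit, train and test."""

    well_id: str
    n_train: int
    n_test: int
    train_nrmse: np.ndarray
    test_nrmse: np.ndarray
    train_prop_correct: np.ndarray
    test_prop_correct: np.ndarray
    test_pct_dry_when_flooded: float
    test_pct_flooded_when_dry: float

    def _dist(self, x: np.ndarray) -> dict:
        lo, hi = hpd_interval(x, 0.95)
        return {
            "median": float(np.median(x)),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "variance": float(np.var(x, ddof=1)),
            # the same spread on a percentage scale, for comparability with
            # reports quoting variances of percent-correct
            "variance_pct_scale": float(np.var(100.0 * x, ddof=1)),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "train_nrmse": self._dist(self.train_nrmse),
            "test_nrmse": self._dist(self.test_nrmse),
            "train_prop_correct": self._dist(self.train_prop_correct),
            "test_prop_correct": self._dist(self.test_prop_correct),
        }
        df = pd.DataFrame(rows).T
        df["well_id"] = self.well_id
        df["n_train"] = self.n_train
        df["n_test"] = self.n_test
        return df


def validate(
    results: WetlandLevelResults,
    covariates: pd.DataFrame,
    split: SplitSpec | None = None,
    free_running_test: bool = False,
    well_id: str = "well",
) -> ValidationReport:
    """Run the consecutive-split validation protocol for a fitted model.

    ``covariates`` must carry ``level_mm`` (the observed response) alongside
    the regressors.  The normalization range for NRMSE is the range of ALL
    measured levels in the basin (train and test together).  When
    ``free_running_test`` is set, test predictions recurse on the model's own
    output within each contiguous test block instead of using observed lags.
    """
    if "level_mm" not in covariates.columns:
        raise ValueError("covariates must carry the observed level_mm column")
    train, test = split_train_test(covariates, split)
    level_range = float(
        covariates["level_mm"].max() - covariates["level_mm"].min()
    )

    draws = results.draws
    pred_train = predict_one_step(draws, train)
    if free_running_test:
        preds = []
        for block in _contiguous_blocks(test):
            init = float(block["lag_level_mm"].iloc[0])
            preds.append(predict_free_running(draws, block, init))
        pred_test = np.hstack(preds)
    else:
        pred_test = predict_one_step(draws, test)

    y_train = train["level_mm"].to_numpy(dtype=float)
    y_test = test["level_mm"].to_numpy(dtype=float)
    train_nr = nrmse(y_train, pred_train, level_range)
    test_nr = nrmse(y_test, pred_test, level_range)
    train_acc, _, _ = wet_dry_accuracy(y_train, pred_train)
    test_acc, dwf, fwd = wet_dry_accuracy(y_test, pred_test)
    return ValidationReport(
        well_id=well_id,
        n_train=len(train),
        n_test=len(test),
        train_nrmse=train_nr,
        test_nrmse=test_nr,
        train_prop_correct=train_acc,
        test_prop_correct=test_acc,
        test_pct_dry_when_flooded=float(dwf.mean()),
        test_pct_flooded_when_dry=float(fwd.mean()),
    )


def _contiguous_blocks(rows: pd.DataFrame):
    dates = pd.to_datetime(rows["date"])
    breaks = np.flatnonzero(dates.diff().iloc[1:] != pd.Timedelta(days=1)) + 1
    start = 0
    for b in list(breaks) + [len(rows)]:
        yield rows.iloc[start:b]
        start = b
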