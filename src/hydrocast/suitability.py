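"""Flatwoods-salamander breeding-suitability metrics from daily water levels.

The reticulated flatwoods salamander (*Ambystoma bishopi*) breeds in
ephemeral wetlands between 1 November and 31 May: eggs laid in dry basins
hatch on inundation, and larvae need roughly 15 consecutive flooded weeks
(105 days; reported extremes 11-18 weeks) to reach metamorphosis.  A season
is scored by

* the maximum hydroperiod -- the longest run of consecutive days with
  standing water (level > 0 mm) inside the season window;
* the fill day -- the start of that longest run, in days after 1 November
  (0-based);
* a suitability flag -- maximum hydroperiod >= the threshold (default 105).

Across a posterior-draw ensemble of projected trajectories, population-level
risk is summarized by the median count of suitable seasons and the proportion
of draws with at least five consecutive unsuitable seasons (an extended
reproductive failure thought to threaten population persistence); a wetland
is flagged at risk when that proportion exceeds 0.75 or the median suitable
count falls below 15 seasons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import ScenarioEnsemble

__all__ = [
    "SeasonSummary",
    "RiskSummary",
    "season_windows",
    "max_hydroperiod",
    "suitability",
    "season_table",
    "max_consecutive_failures",
    "risk_summary",
    "observed_record_summary",
    "BREEDING_SEASON_START",
    "BREEDING_SEASON_END",
    "SUITABLE_HYDROPERIOD_DAYS",
]

#: Breeding-season window (month, day)
BREEDING_SEASON_START = (11, 1)
BREEDING_SEASON_END = (5, 31)
#: Conservative hydroperiod (days) needed for larval development: 15 weeks
SUITABLE_HYDROPERIOD_DAYS = 105


@dataclass(frozen=True)
class SeasonSummary:
    """Breeding-season score: season labelled by its starting calendar year."""

    season_year: int
    max_hydroperiod_days: int
    fill_day_offset: int | None  # days after 1 Nov; None if never flooded
    suitable: bool


@dataclass(frozen=True)
class RiskSummary:
    """Cross-draw persistence-risk summary for one wetland x scenario."""

    median_suitable_seasons: float
    prop_consecutive_failures: float
    failure_run_years: int
    n_seasons: int
    n_draws: int
    at_risk: bool


def season_windows(dates: pd.DatetimeIndex):
    """Boolean masks of complete breeding seasons (1 Nov - 31 May) in ``dates``.

    Returns ``(windows, n_partial)`` where ``windows`` is a list of
    ``(season_year, mask)`` pairs for seasons fully contained in the record
    (length 212, or 213 when February of the ending year is leap), and
    ``n_partial`` counts seasons excluded for incomplete coverage.
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("empty date index")
    deltas = np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        raise ValueError("dates must be contiguous daily values")
    windows = []
    n_partial = 0
    for year in range(dates[0].year - 1, dates[-1].year + 1):
        start = pd.Timestamp(year, *BREEDING_SEASON_START)
        end = pd.Timestamp(year + 1, *BREEDING_SEASON_END)
        if start > dates[-1] or end < dates[0]:
            continue
        if start < dates[0] or end > dates[-1]:
            n_partial += 1
            continue
        mask = (dates >= start) & (dates <= end)
        windows.append((year, mask))
    return windows, n_partial


def max_hydroperiod(levels) -> tuple:
    """Longest run of consecutive flooded days (level > 0 mm) in a season.

    Returns ``(length_days, start_offset)`` where ``start_offset`` is the
    0-based index of the run's first day within the season (days after
    1 Nov); ties go to the earliest run; ``(0, None)`` if never flooded.
    """
    wet = np.asarray(levels, dtype=float) > 0
    if wet.size == 0:
        raise ValueError("empty season")
    if not wet.any():
        return 0, None
    padded = np.concatenate([[0], wet.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    j = int(np.argmax(lengths))  # argmax takes the first (earliest) maximum
    return int(lengths[j]), int(starts[j])


def suitability(max_hydroperiod_days: int, threshold_days: int = SUITABLE_HYDROPERIOD_DAYS) -> bool:
    """True iff the season's maximum hydroperiod reaches the threshold."""
    return bool(max_hydroperiod_days >= threshold_days)


def season_table(
    ens: ScenarioEnsemble,
    threshold_days: int = SUITABLE_HYDROPERIOD_DAYS,
) -> pd.DataFrame:
    """Per-draw, per-season summaries for a projected ensemble.

    Returns a long DataFrame with columns draw, season_year,
    max_hydroperiod_days, fill_day_offset (NaN when never flooded), suitable.
    Partial seasons at the record edges are excluded; their count is stored
    in ``result.attrs['n_partial_seasons']``.
    """
    windows, n_partial = season_windows(ens.dates)
    if not windows:
        raise ValueError("no complete breeding season in the projection window")
    records = []
    for year, mask in windows:
        block = ens.levels[:, mask]
        for i, draw in enumerate(ens.draw_indices):
            length, start = max_hydroperiod(block[i])
            records.append(
                (
                    draw,
                    year,
                    length,
                    np.nan if start is None else start,
                    length >= threshold_days,
                )
            )
    out = pd.DataFrame.from_records(
        records,
        columns=["draw", "season_year", "max_hydroperiod_days", "fill_day_offset", "suitable"],
    )
    out.attrs["n_partial_seasons"] = n_partial
    return out


def max_consecutive_failures(suitable_flags) -> int:
    """Longest run of consecutive unsuitable seasons."""
    flags = np.asarray(suitable_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one season")
    fail = ~flags
    if not fail.any():
        return 0
    padded = np.concatenate([[0], fail.astype(int), [0]])
    d = np.diff(padded)
    lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return int(lengths.max())


def risk_summary(
    seasons: pd.DataFrame,
    failure_run_years: int = 5,
    thresholds: tuple = (0.75, 15),
) -> RiskSummary:
    """Cross-draw persistence risk from a per-draw season table.

    * ``prop_consecutive_failures``: share of draws whose longest run of
      unsuitable seasons reaches ``failure_run_years``;
    * ``median_suitable_seasons``: median over draws of the count of suitable
      seasons over the horizon;
    * ``at_risk``: the proportion exceeds ``thresholds[0]`` or the median
      falls below ``thresholds[1]`` suitable seasons.
    """
    if seasons.empty:
        raise ValueError("empty season table")
    ordered = seasons.sort_values(["draw", "season_year"])
    by_draw = ordered.groupby("draw")["suitable"]
    runs = by_draw.apply(lambda s: max_consecutive_failures(s.to_numpy()))
    counts = by_draw.sum()
    prop = float((runs >= failure_run_years).mean())
    median_suitable = float(counts.median())
    return RiskSummary(
        median_suitable_seasons=median_suitable,
        prop_consecutive_failures=prop,
        failure_run_years=failure_run_years,
        n_seasons=int(seasons["season_year"].nunique()),
        n_draws=int(counts.size),
        at_risk=bool(prop > thresholds[0] or median_suitable < thresholds[1]),
    )


def observed_record_summary(levels: pd.DataFrame) -> dict:
    """Summary counts of an observed multi-well water-level panel.

    Expects a long table (date, well_id, level_mm).  Reports the total
    number of daily observations, the per-well record-count extremes, the
    range over wells of the mean (across seasons) breeding-season maximum
    hydroperiod, and the range over seasons of the mean (across wells)
    maximum hydroperiod.  Wells contribute a season only when their record
    covers it fully.
    """
    required = {"date", "well_id", "level_mm"}
    if not required.issubset(levels.columns):
        raise ValueError(f"panel needs columns {sorted(required)}")
    counts = levels.groupby("well_id")["level_mm"].count()
    per_season = []
    for well, grp in levels.groupby("well_id"):
        grp = grp.sort_values("date")
        dates = pd.DatetimeIndex(pd.to_datetime(grp["date"]))
        vals = grp["level_mm"].to_numpy(dtype=float)
        windows, _ = season_windows(dates)
        for year, mask in windows:
            length, _ = max_hydroperiod(vals[mask])
            per_season.append((well, year, length))
    hp = pd.DataFrame(per_season, columns=["well_id", "season_year", "max_hydroperiod_days"])
    out = {
        "n_observations": int(len(levels)),
        "min_records_per_well": int(counts.min()),
        "max_records_per_well": int(counts.max()),
    }
    if not hp.empty:
        by_well = hp.groupby("well_id")["max_hydroperiod_days"].mean()
        by_year = hp.groupby("season_year")["max_hydroperiod_days"].mean()
        out.update(
            mean_hydroperiod_by_well_min=float(by_well.min()),
            mean_hydroperiod_by_well_max=float(by_well.max()),
            mean_hydroperiod_by_year_min=float(by_year.min()),
            mean_hydroperiod_by_year_max=float(by_year.max()),
        )
    return out
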