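"""Reproducible end-to-end runs: configuration, seeding, manifests.

A single :class:`RunConfig` (readable from a TOML file) drives the whole
chain: (synthetic data ->) covariates -> fit -> validate -> project ->
suitability metrics.  One master seed deterministically derives a seed per
stage, so identical configs give byte-identical outputs.  Every stage writes
its CSV products plus a small JSON manifest (inputs, seed, config hash) into
the run directory; a stage failure aborts the run with the failing stage
named.

All dates are serialized ISO-8601; levels are mm, temperatures degC, PET
mm/day -- units are embedded in the column names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import suitability as suit_mod
from .model import McmcConfig, PriorSpec, PosteriorDraws, fit_model
from .projection import project
from .synthetic import ClimateGenConfig, TrueParams, generate_scenario, simulate_water_levels, generate_climate
from .validation import SplitSpec, validate

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ["simulate_data", "covariates", "fit", "validate", "project", "metrics"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``levels_path``/``climate_path`` are unset, a synthetic well is
    simulated from ``climate_gen``/``true_params`` so the pipeline runs with
    no external data.  ``scenario_trends`` maps scenario labels to
    (degC-per-decade, precipitation-multiplier) pairs applied by the
    synthetic scenario generator; alternatively ``scenario_paths`` provides
    ready-made climate tables with the same schema as the observed climate.
    """

    latitude_deg: float = 30.5
    levels_path: str | None = None
    climate_path: str | None = None
    scenario_paths: dict = field(default_factory=dict)
    scenario_trends: dict = field(
        default_factory=lambda: {"warm-dry": (0.4, 0.9), "neutral": (0.0, 1.0)}
    )
    projection_years: tuple = (2025, 2100)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    climate_gen: ClimateGenConfig = field(default_factory=ClimateGenConfig)
    true_params: TrueParams = field(default_factory=TrueParams)
    levels_start_year: int = 2015  # synthetic monitoring record start
    init_level_mm: float = 0.0
    include_process_noise: bool = True
    n_projection_draws: int | None = 1000
    hydroperiod_threshold_days: int = 105
    failure_run_years: int = 5
    risk_prop_cutoff: float = 0.75
    risk_median_cutoff: float = 15
    seed: int = 0

    def __post_init__(self):
        if self.hydroperiod_threshold_days <= 0 or self.failure_run_years <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        for key, sub in [
            ("mcmc", McmcConfig),
            ("priors", PriorSpec),
            ("split", SplitSpec),
            ("climate_gen", ClimateGenConfig),
            ("true_params", TrueParams),
        ]:
            if key in raw:
                val = raw[key]
                if key == "climate_gen" and "wet_day_prob_by_month" in val:
                    val["wet_day_prob_by_month"] = tuple(val["wet_day_prob_by_month"])
                raw[key] = sub(**val)
        if "scenario_trends" in raw:
            raw["scenario_trends"] = {
                k: tuple(v) for k, v in raw["scenario_trends"].items()
            }
        if "projection_years" in raw:
            raw["projection_years"] = tuple(raw["projection_years"])
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o).__name__)

        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31))


def _require_columns(df: pd.DataFrame, cols, stage: str, what: str):
    missing = sorted(set(cols).difference(df.columns))
    if missing:
        raise PipelineError(
            f"stage '{stage}': {what} is missing required columns {missing}"
        )


def _write_manifest(out_dir: Path, stage: str, cfg: RunConfig, seed: int, outputs, inputs=()):
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    path = out_dir / f"{stage}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, index=False, date_format="%Y-%m-%d")


def read_csv(path) -> pd.DataFrame:
    """Read a pipeline CSV (skipping the config-hash comment line)."""
    df = pd.read_csv(path, comment="#")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage: simulate_data (or load user tables)
    stage = "simulate_data"
    try:
        seed = config.stage_seed(stage)
        if config.climate_path:
            climate = read_csv(config.climate_path)
        else:
            climate = generate_climate(config.climate_gen)
        _require_columns(climate, ["date", "precip_mm", "tmin_c", "tmax_c"], stage, "climate table")
        if config.levels_path:
            levels = read_csv(config.levels_path)
            _require_columns(levels, ["date", "well_id", "level_mm"], stage, "level table")
        else:
            levels = _simulate_levels(config, climate, seed)
        written = [out / "climate.csv", out / "levels.csv"]
        _write_csv(climate, written[0], config)
        _write_csv(levels, written[1], config)
        _write_manifest(out, stage, config, seed, written,
                        [p for p in (config.climate_path, config.levels_path) if p])
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    # ---- stage: covariates
    stage = "covariates"
    try:
        balance = climate_mod.monthly_water_balance(climate, config.latitude_deg)
        spei_12 = climate_mod.spei(balance, scale=12)
        well = levels[["date", "level_mm"]].reset_index(drop=True)
        cov = climate_mod.build_covariates(well, climate, config.latitude_deg, spei_12)
        cov_path = out / "covariates.csv"
        _write_csv(cov, cov_path, config)
        _write_manifest(out, stage, config, config.stage_seed(stage), [cov_path],
                        [out / "climate.csv", out / "levels.csv"])
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    # ---- stage: fit
    stage = "fit"
    try:
        seed = config.stage_seed(stage)
        mcmc = dataclasses.replace(config.mcmc, seed=seed)
        results = fit_model(cov, priors=config.priors, mcmc=mcmc)
        draws_path = out / "posterior_draws.csv"
        diag_path = out / "fit_diagnostics.csv"
        _write_csv(results.draws.to_dataframe(), draws_path, config)
        diag = results.diagnostics().reset_index(names="parameter")
        diag["bayesian_p"] = results.bayesian_p_value(seed=seed)
        _write_csv(diag, diag_path, config)
        _write_manifest(out, stage, config, seed, [draws_path, diag_path], [cov_path])
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    # ---- stage: validate
    stage = "validate"
    try:
        seed = config.stage_seed(stage)
        split = dataclasses.replace(config.split, seed=seed)
        report = validate(results, cov, split=split,
                          well_id=str(levels["well_id"].iloc[0]))
        rep_path = out / "validation.csv"
        frame = report.to_frame().reset_index(names="quantity")
        frame["test_pct_dry_when_flooded"] = report.test_pct_dry_when_flooded
        frame["test_pct_flooded_when_dry"] = report.test_pct_flooded_when_dry
        _write_csv(frame, rep_path, config)
        _write_manifest(out, stage, config, seed, [rep_path], [draws_path, cov_path])
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    # ---- stage: project + metrics
    stage = "project"
    try:
        seed = config.stage_seed(stage)
        scenarios = _scenario_tables(config)
        n_sub = config.n_projection_draws
        if n_sub is not None and n_sub < results.draws.n_draws:
            rng = np.random.default_rng(seed)
            draw_idx = np.sort(rng.choice(results.draws.n_draws, n_sub, replace=False))
        else:
            draw_idx = None
        ensembles = {}
        proj_paths = []
        for i, (name, table) in enumerate(sorted(scenarios.items())):
            ens = project(
                results.draws,
                table,
                config.latitude_deg,
                init_level=config.init_level_mm,
                include_process_noise=config.include_process_noise,
                seed=seed + i + 1,
                scenario_id=name,
                well_id=str(levels["well_id"].iloc[0]),
                draw_indices=draw_idx,
            )
            ensembles[name] = ens
            from .projection import ensemble_summary

            band_path = out / f"projection_{name}.csv"
            _write_csv(
                ensemble_summary(ens, (0.05, 0.25, 0.5, 0.75, 0.95))
                .reset_index(names="date"),
                band_path, config,
            )
            proj_paths.append(band_path)
        _write_manifest(out, stage, config, seed, proj_paths, [draws_path])
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    stage = "metrics"
    try:
        seed = config.stage_seed(stage)
        season_paths = []
        risk_rows = []
        for name, ens in sorted(ensembles.items()):
            seasons = suit_mod.season_table(ens, config.hydroperiod_threshold_days)
            sp = out / f"seasons_{name}.csv"
            _write_csv(seasons, sp, config)
            season_paths.append(sp)
            risk = suit_mod.risk_summary(
                seasons,
                failure_run_years=config.failure_run_years,
                thresholds=(config.risk_prop_cutoff, config.risk_median_cutoff),
            )
            risk_rows.append({"scenario": name, **dataclasses.asdict(risk)})
        risk_path = out / "risk_summary.csv"
        _write_csv(pd.DataFrame(risk_rows), risk_path, config)
        _write_manifest(out, stage, config, seed, season_paths + [risk_path], proj_paths)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    return out


def _simulate_levels(config: RunConfig, climate: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Synthetic monitoring record over the tail years of the climate table."""
    balance = climate_mod.monthly_water_balance(climate, config.latitude_deg)
    spei_12 = climate_mod.spei(balance, scale=12)
    feats = climate_mod.precip_features(climate)
    doy = climate["date"].dt.dayofyear.to_numpy()
    pet = climate_mod.hargreaves_samani_daily_pet(
        climate["tmin_c"].to_numpy(), climate["tmax_c"].to_numpy(),
        config.latitude_deg, doy,
    )
    cov = feats.assign(pet_mm_day=pet, pet_sq=pet**2)
    months = cov["date"].dt.to_period("M")
    cov["spei_12"] = spei_12.reindex(months).to_numpy()
    cov = cov.loc[
        (cov["date"] >= pd.Timestamp(config.levels_start_year, 1, 1))
        & cov[["precip_prev_mm", "weekprecip_mm", "pet_mm_day", "spei_12"]]
        .notna().all(axis=1)
    ].reset_index(drop=True)
    if cov.empty:
        raise ValueError("levels_start_year outside the climate record")
    return simulate_water_levels(
        climate, config.true_params, cov,
        init_level=config.init_level_mm, seed=seed,
    )


def _stable_hash(name: str) -> int:
    # process-independent (unlike builtin hash), keeps runs reproducible
    return int(hashlib.sha256(name.encode()).hexdigest()[:8], 16)


def _scenario_tables(config: RunConfig) -> dict:
    if config.scenario_paths:
        tables = {}
        for name, path in config.scenario_paths.items():
            t = read_csv(path)
            _require_columns(t, ["date", "precip_mm", "tmin_c", "tmax_c"],
                             "project", f"scenario table '{name}'")
            tables[name] = t
        return tables
    y0, y1 = config.projection_years
    tables = {}
    for name, (trend_t, trend_p) in config.scenario_trends.items():
        gen = dataclasses.replace(
            config.climate_gen,
            trend_temp_c_per_decade=float(trend_t),
            trend_precip_multiplier=float(trend_p),
            seed=config.stage_seed("project") + _stable_hash(name) % 10_000,
        )
        # one extra lead year so SPEI-12 is defined from 1 Jan of y0
        tables[name] = generate_scenario(gen, range(y0 - 1, y1 + 1))
    return tables
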