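"""Pipeline orchestration: configuration, stage sequencing and manifests.

Stages communicate only through on-disk artifacts (tidy CSV between stages,
NetCDF for gridded fields), so any stage can be re-run standalone or fed
with real vegetation-model / accounts / valuation data through the same
formats.  Re-running with an identical configuration reproduces identical
content hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import (
    attribution,
    biome_accounting,
    damages,
    economy,
    projection,
    synthetic_data,
)
from .config import (
    CAP_AREA_PCT,
    CAP_CARBON_PCT,
    DECADES,
    DELTA_DEPRECIATION,
    DISCOUNT_RATE,
    HORIZON,
    SAVINGS_RATE,
    STEP_YEARS,
    logger,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, YAML-serializable.

    Numeric defaults carry their provenance in :mod:`natcapclim.config`;
    grid/scenario sizes are package decisions tuned for desk-scale runs.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    n_lat: int = 36
    n_lon: int = 72
    n_countries: int = 8
    n_biomes: int = 4
    n_vegs_records: int = 400
    typologies: tuple[str, ...] = ("lpj", "orchidee", "caraib")
    gcms: tuple[str, ...] = ("gcm1", "gcm2", "gcm3", "gcm4")
    rcps: tuple[str, ...] = ("rcp26", "rcp60", "rcp85")
    base_year: int = 2018
    horizon: tuple[int, int] = HORIZON
    decades: tuple[int, ...] = DECADES
    discount_rate: float = DISCOUNT_RATE
    cap_area_pct: float = CAP_AREA_PCT
    cap_carbon_pct: float = CAP_CARBON_PCT
    subset_k: int | None = None
    delta: float = DELTA_DEPRECIATION
    step_years: int = STEP_YEARS
    savings_rate: float = SAVINGS_RATE
    ssp_end_warming: float = 3.0
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.world_config().validate()
        if self.discount_rate <= 0:
            raise ValueError("discount rate must be positive")
        if self.cap_area_pct <= 0 or self.cap_carbon_pct <= 0:
            raise ValueError("caps must be positive")
        if not self.typologies or not self.gcms or not self.rcps:
            raise ValueError("typologies, gcms and rcps must be nonempty")

    def world_config(self) -> synthetic_data.WorldConfig:
        return synthetic_data.WorldConfig(
            n_lat=self.n_lat, n_lon=self.n_lon, n_countries=self.n_countries,
            n_biomes=self.n_biomes, seed=self.seed,
            horizon_years=tuple(self.horizon))

    def planted_truth(self) -> synthetic_data.PlantedTruth:
        return synthetic_data.PlantedTruth(**self.truth)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("typologies", "gcms", "rcps", "horizon", "decades"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @property
    def eval_years(self) -> list[int]:
        # decade midpoints, evaluated at decade-mean anomalies
        return [d + 5 for d in self.decades]


def _out(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_synth(config: RunConfig) -> list[str]:
    """Generate and write every synthetic input."""
    out = _out(config)
    world = synthetic_data.make_world(config.world_config(),
                                      config.planted_truth())
    paths = list(synthetic_data.save_world(world, out).values())

    vegs = synthetic_data.make_vegs_table(world, n_obs=config.n_vegs_records)
    vegs_path = out / "vegs.csv"
    vegs.to_csv(vegs_path, index=False)
    paths.append(str(vegs_path))

    accounts = synthetic_data.make_accounts(world, base_year=config.base_year)
    for name, df in (("accounts", accounts.accounts.reset_index()),
                     ("trajectories", accounts.trajectories),
                     ("panel", accounts.panel)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(str(p))

    runs = synthetic_data.make_run_matrix(config.gcms, config.rcps)
    temp_rows = []
    for _, run in runs.iterrows():
        s = run["path"].series
        temp_rows.append(pd.DataFrame({"run_id": run["run_id"],
                                       "gcm": run["gcm"], "rcp": run["rcp"],
                                       "year": s.index, "dT": s.values}))
    temps_path = out / "temperature.csv"
    pd.concat(temp_rows, ignore_index=True).to_csv(temps_path, index=False)
    paths.append(str(temps_path))

    # per-run vegetation response at the base year + decade midpoints,
    # using decade-mean anomalies at the midpoint years
    years = [config.base_year] + config.eval_years
    for _, run in runs.iterrows():
        path = run["path"]
        series = pd.Series(
            [0.0] + [path.decade_mean(d) for d in config.decades], index=years)
        eval_path = synthetic_data.TemperaturePath(series)
        ds = synthetic_data.simulate_vegetation(world, eval_path)
        p = out / f"vegetation_{run['run_id']}.nc"
        ds.to_netcdf(p)
        paths.append(str(p))
    return paths


def _load_world_bits(out: Path):
    grid = biome_accounting.read_grid(out / "base_grid.nc")
    mask = biome_accounting.read_mask(out / "country_mask.nc")
    return grid, mask


def stage_aggregate(config: RunConfig) -> list[str]:
    """Country-by-biome areas for the base year and every run/eval year."""
    out = _out(config)
    grid, mask = _load_world_bits(out)
    base = biome_accounting.aggregate_to_country(grid["cover"], grid["carbon"],
                                                 mask)
    tidy = [base.by_biome.assign(run_id="base", year=config.base_year)]
    ctry = [base.by_country.reset_index().assign(run_id="base",
                                                 year=config.base_year)]
    runs = pd.read_csv(out / "temperature.csv")["run_id"].unique()
    for run_id in runs:
        ds = xr.open_dataset(out / f"vegetation_{run_id}.nc")
        aggs = biome_accounting.aggregate_series(ds, mask)
        for year, agg in aggs.items():
            tidy.append(agg.by_biome.assign(run_id=run_id, year=year))
            ctry.append(agg.by_country.reset_index().assign(run_id=run_id,
                                                            year=year))
    p1 = out / "areas_by_biome.csv"
    pd.concat(tidy, ignore_index=True).to_csv(p1, index=False)
    p2 = out / "areas_by_country.csv"
    pd.concat(ctry, ignore_index=True).to_csv(p2, index=False)
    return [str(p1), str(p2)]


def _areas_from_csv(by_biome: pd.DataFrame, by_country: pd.DataFrame,
                    run_id: str, year: int) -> biome_accounting.CountryBiomeAreas:
    bb = by_biome[(by_biome.run_id == run_id) & (by_biome.year == year)]
    bc = by_country[(by_country.run_id == run_id) & (by_country.year == year)]
    if bb.empty or bc.empty:
        raise StageError(f"no aggregated areas for run {run_id} year {year}")
    return biome_accounting.CountryBiomeAreas(
        year=year,
        by_biome=bb[["country", "biome", "hectares", "year"]].copy(),
        by_country=bc.set_index("country")[
            ["territory_ha", "total_veg_ha", "perc_covered", "mean_carbon",
             "year"]].copy(),
    )


def stage_attribute(config: RunConfig) -> list[str]:
    """Apportion national stocks to biomes and estimate elasticities."""
    out = _out(config)
    vegs = pd.read_csv(out / "vegs.csv")
    accounts = pd.read_csv(out / "accounts.csv").set_index("country")
    by_biome = pd.read_csv(out / "areas_by_biome.csv")
    by_country = pd.read_csv(out / "areas_by_country.csv")
    base = _areas_from_csv(by_biome, by_country, "base", config.base_year)

    result = attribution.attribute_all(
        vegs, base, accounts, typologies=config.typologies,
        r=config.discount_rate, k=config.subset_k, seed=config.seed)
    p1 = out / "per_hectare_values.csv"
    result.per_hectare.to_csv(p1, index=False)
    p2 = out / "scaling_factors.csv"
    result.scaling.to_csv(p2, index=False)

    elas = attribution.estimate_elasticities(vegs)
    p3 = out / "elasticities.csv"
    elas.table.to_csv(p3, index=False)
    p4 = out / "elasticities.json"
    with open(p4, "w") as fh:
        json.dump(elas.table.to_dict(orient="records"), fh, indent=1)
    return [str(p1), str(p2), str(p3), str(p4)]


def stage_project(config: RunConfig, typology: str | None = None) -> list[str]:
    """Natural-capital trajectories and normalized changes per run."""
    out = _out(config)
    typology = typology or config.typologies[0]
    per_hectare = pd.read_csv(out / "per_hectare_values.csv")
    by_biome = pd.read_csv(out / "areas_by_biome.csv")
    by_country = pd.read_csv(out / "areas_by_country.csv")
    base = _areas_from_csv(by_biome, by_country, "base", config.base_year)

    elas = pd.read_csv(out / "elasticities.csv")
    nm = elas[elas.benefit_type == "non-market"].set_index("term")
    eta_a = float(nm.loc["area", "coef"])
    eta_c = float(nm.loc["carbon", "coef"])

    run_ids = by_biome[by_biome.run_id != "base"]["run_id"].unique()
    traj_frames, change_frames = [], []
    for run_id in run_ids:
        years = sorted(by_biome[by_biome.run_id == run_id]["year"].unique())
        aggs = {y: _areas_from_csv(by_biome, by_country, run_id, y)
                for y in years}
        traj = projection.project_run(
            aggs, per_hectare, base, r=config.discount_rate,
            eta_area=eta_a, eta_carbon=eta_c,
            cap_a=config.cap_area_pct, cap_c=config.cap_carbon_pct,
            typology=typology)
        traj_frames.append(traj.assign(run_id=run_id))
        changes = projection.normalize_changes(traj, base_year=config.base_year)
        change_frames.append(changes.assign(run_id=run_id))
    p1 = out / "natcap_trajectories.csv"
    pd.concat(traj_frames, ignore_index=True).to_csv(p1, index=False)
    p2 = out / "natcap_changes.csv"
    pd.concat(change_frames, ignore_index=True).to_csv(p2, index=False)
    return [str(p1), str(p2)]


def _runs_table(out: Path) -> pd.DataFrame:
    temps = pd.read_csv(out / "temperature.csv")
    rows = []
    for run_id, grp in temps.groupby("run_id"):
        path = synthetic_data.TemperaturePath(
            pd.Series(grp["dT"].to_numpy(), index=grp["year"].to_numpy()))
        rows.append({"run_id": run_id, "gcm": grp["gcm"].iloc[0],
                     "rcp": grp["rcp"].iloc[0], "path": path})
    return pd.DataFrame(rows)


def stage_damages(config: RunConfig, typology: str | None = None) -> list[str]:
    """Fit the per-country damage functions."""
    out = _out(config)
    typology = typology or config.typologies[0]
    changes = pd.read_csv(out / "natcap_changes.csv")
    changes = changes[changes.year != config.base_year]
    runs = _runs_table(out)
    panel = damages.assemble_panel(changes, runs, config.decades)
    p1 = out / "damage_panel.csv"
    panel.to_csv(p1, index=False)
    table = damages.fit_all(panel, typology=typology)
    p2 = out / "damage_coefficients.csv"
    table.to_csv(p2, index=False)
    return [str(p1), str(p2)]


def stage_simulate(config: RunConfig) -> list[str]:
    """Baseline and damaged economy runs plus impact summaries."""
    out = _out(config)
    accounts = pd.read_csv(out / "accounts.csv").set_index("country")
    traj = pd.read_csv(out / "trajectories.csv")
    theta = pd.read_csv(out / "damage_coefficients.csv")

    step_yrs = list(range(config.horizon[0], config.horizon[1] + 1,
                          config.step_years))
    labour = traj.pivot(index="year", columns="country",
                        values="labour").loc[step_yrs]
    gdp_target = traj.pivot(index="year", columns="country",
                            values="gdp_baseline").loc[step_yrs]
    pop = traj.pivot(index="year", columns="country",
                     values="population").loc[step_yrs]

    tfp, _ = economy.calibrate_tfp(
        gdp_target, labour, accounts["manufactured_capital"],
        accounts["market_natcap"], accounts["nonmarket_natcap"], accounts,
        savings=config.savings_rate, delta=config.delta,
        step_years=config.step_years)

    ssp_path = synthetic_data.make_temperature_path(
        range(config.horizon[0], config.horizon[1] + 1),
        end_warming=config.ssp_end_warming)
    base_run = economy.simulate(accounts, tfp, labour, mode="baseline",
                                savings=config.savings_rate,
                                delta=config.delta,
                                step_years=config.step_years,
                                r=config.discount_rate)
    dam_run = economy.simulate(accounts, tfp, labour, theta=theta,
                               temp_path=ssp_path, mode="damaged",
                               savings=config.savings_rate,
                               delta=config.delta,
                               step_years=config.step_years,
                               r=config.discount_rate)
    p1 = out / "economy_trajectories.csv"
    pd.concat([base_run, dam_run], ignore_index=True).to_csv(p1, index=False)

    summary = economy.impacts(base_run, dam_run, pop,
                              eval_year=config.horizon[1])
    p2 = out / "impacts.csv"
    summary.by_country.to_csv(p2, index=False)

    at = summary.by_country[summary.by_country.year == summary.eval_year]
    losses = at.set_index("country")["gdp_loss"]
    base_at = base_run[base_run.year == summary.eval_year].set_index("country")
    gdppc = base_at["gdp"] / base_at["labour"]
    dist = economy.damage_distribution(losses, gdppc,
                                       pop.loc[summary.eval_year])
    p3 = out / "impact_summary.json"
    with open(p3, "w") as fh:
        json.dump(
            {
                "eval_year": summary.eval_year,
                "global_pct_gdp": summary.global_pct_gdp,
                "global_pct_es": summary.global_pct_es,
                "bottom50_damage_share": dist["bottom_share"],
                "top10_damage_share": dist["top_share"],
            },
            fh, indent=1)
    return [str(p1), str(p2), str(p3)]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

STAGES = (
    ("synth", stage_synth),
    ("aggregate", stage_aggregate),
    ("attribute", stage_attribute),
    ("project", stage_project),
    ("damages", stage_damages),
    ("simulate", stage_simulate),
)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every stage in order; returns the artifact manifest.

    A stage failure aborts the run with the failing stage named; artifacts
    written before the failure are flagged stale in the raised error.
    """
    config.validate()
    out = _out(config)
    config.to_yaml(out / "run_config.yaml")
    written: list[str] = [str(out / "run_config.yaml")]
    for name, fn in STAGES:
        logger.info("pipeline stage=%s starting", name)
        try:
            written.extend(fn(config))
        except Exception as exc:
            raise StageError(
                f"stage {name!r} failed ({exc}); artifacts written so far "
                f"are stale: {written}") from exc
    manifest = pd.DataFrame(
        {"artifact": [Path(p).name for p in written],
         "path": written,
         "sha256": [sha256_of(p) for p in written]}
    ).sort_values("artifact").reset_index(drop=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema / unit / invariant checks on pipeline inputs.

    ``paths`` may carry any of: grid (NetCDF), mask (NetCDF), vegs (CSV),
    accounts (CSV).  Returns the list of violations (empty = valid).
    """
    report: list[str] = []
    if "grid" in paths:
        try:
            biome_accounting.read_grid(paths["grid"])
        except (ValueError, OSError) as exc:
            report.append(f"grid: {exc}")
    if "mask" in paths:
        try:
            mask = biome_accounting.read_mask(paths["mask"])
            if not np.issubdtype(mask.dtype, np.integer):
                report.append("mask: country identifiers must be integers")
        except (KeyError, OSError) as exc:
            report.append(f"mask: {exc}")
    if "vegs" in paths:
        vegs = pd.read_csv(paths["vegs"])
        need = {"benefit_type", "value_per_ha_yr", "gdp_pc", "perc_covered",
                "site_area_ha", "carbon_kg_m2"}
        missing = need - set(vegs.columns)
        if missing:
            report.append(f"vegs: missing columns {sorted(missing)}")
        elif (vegs["value_per_ha_yr"] <= 0).any():
            report.append("vegs: non-positive value per hectare")
    if "accounts" in paths:
        acc = pd.read_csv(paths["accounts"])
        for col in ("market_natcap", "nonmarket_natcap", "gdp", "population"):
            if col in acc.columns and (acc[col] <= 0).any():
                report.append(f"accounts: non-positive {col}")
            elif col not in acc.columns:
                report.append(f"accounts: missing column {col}")
    return report
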