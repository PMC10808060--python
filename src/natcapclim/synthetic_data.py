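"""Synthetic world generator with planted, recoverable structure.

This module emulates every external input of the pipeline so that each stage
can be tested end to end with no downloads:

* a gridded world of fractional biome cover and vegetation carbon (the
  vegetation-model output surrogate, 0.5-degree-style regular grid),
* a country mask of contiguous regions tiling the vegetated grid,
* a valuation table of per-hectare ecosystem-service values with known
  area / carbon / income elasticities planted on the log scale,
* national wealth accounts (market and non-market natural capital, human and
  manufactured capital, GDP, population) plus socioeconomic trajectories and
  an estimation panel generated from a planted Cobb-Douglas production
  structure,
* global mean temperature anomaly paths for a configurable scenario matrix.

Everything is a pure function of ``(config, truth, seed)``: a fixed master
seed yields byte-identical outputs, and per-generator seeds are derived
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .config import (
    BASE_PERIOD,
    ETA_AREA,
    ETA_CARBON,
    ETA_INCOME,
    HORIZON,
    MACRO_REGIONS,
    SAVINGS_RATE,
    logger,
)

NO_COUNTRY = -1  # mask value for non-vegetated / unassigned cells


class ConfigurationError(ValueError):
    """Invalid world or planted-truth configuration."""


class InputError(ValueError):
    """A required input (for example a temperature anomaly) is missing."""


# ---------------------------------------------------------------------------
# Configuration and planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and size of the synthetic world.

    The default 36 x 72 grid (5-degree cells), 8 countries and 4 biomes keep
    full-pipeline runs in the seconds range while preserving the latitudinal
    structure of real vegetation-model output.
    """

    n_lat: int = 36
    n_lon: int = 72
    n_countries: int = 8
    n_biomes: int = 4
    seed: int = 0
    horizon_years: tuple[int, int] = HORIZON
    base_period: tuple[int, int] = BASE_PERIOD

    def validate(self) -> None:
        if self.n_lat < 2 or self.n_lon < 2:
            raise ConfigurationError("grid must be at least 2 x 2")
        if self.n_countries < 2:
            raise ConfigurationError("need at least 2 countries")
        if self.n_biomes < 1:
            raise ConfigurationError("need at least 1 biome")
        if self.n_countries > self.n_lat * self.n_lon:
            raise ConfigurationError(
                f"cannot tile {self.n_countries} countries onto "
                f"{self.n_lat * self.n_lon} cells"
            )

    @property
    def lat(self) -> np.ndarray:
        step = 180.0 / self.n_lat
        return -90.0 + step * (np.arange(self.n_lat) + 0.5)

    @property
    def lon(self) -> np.ndarray:
        step = 360.0 / self.n_lon
        return -180.0 + step * (np.arange(self.n_lon) + 0.5)

    @property
    def biomes(self) -> list[str]:
        return [f"biome_{b}" for b in range(self.n_biomes)]

    @property
    def countries(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_countries)]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth parameters planted in every synthetic input.

    The valuation elasticities default to the point values the attribution
    stage is meant to recover (area -0.103, carbon 0.282, income 0.00596 for
    non-market benefits; null for market benefits).  Cover and carbon
    sensitivities are fractional changes per degree C of warming; production
    parameters define a constant-returns Cobb-Douglas economy with a
    region-specific elasticity to the global environmental good.
    """

    eta_area: float = ETA_AREA
    eta_carbon: float = ETA_CARBON
    eta_income: float = ETA_INCOME
    eta_area_market: float = 0.0
    eta_carbon_market: float = 0.0
    #: log-scale sd of the valuation-record noise
    noise_sd: float = 0.5
    #: fractional biome-cover change per degree C; scalar, a
    #: (n_countries, n_biomes) array, or None for the default income
    #: gradient (poor countries lose cover under warming, the richest
    #: marginally gain, emulating the poleward-shift pattern)
    cover_sensitivity: float | np.ndarray | None = None
    #: fractional vegetation-carbon change per degree C
    carbon_sensitivity: float = 0.02
    #: additive cover noise sd (cover-fraction units) and carbon noise sd
    cover_noise_sd: float = 0.0
    carbon_noise_sd: float = 0.0
    #: per-biome weights of the cover term in the planted log-value model
    biome_value_weights: np.ndarray | None = None
    #: production: labour elasticity and region -> elasticity of the global
    #: environmental good
    gamma1: float = 0.5
    b_region: dict[str, float] = field(
        default_factory=lambda: {
            "ASIA": 0.30,
            "LAM": 0.25,
            "MAF": 0.35,
            "OECD": 0.15,
            "REF": 0.20,
        }
    )
    #: GDP-per-capita span across countries (poorest, richest)
    gdppc_range: tuple[float, float] = (1_000.0, 40_000.0)
    #: log-scale sd of the GDP noise in the estimation panel
    gdp_noise_sd: float = 0.01

    def validate(self) -> None:
        if self.noise_sd < 0 or self.cover_noise_sd < 0 or self.carbon_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not 0 < self.gamma1 < 1:
            raise ConfigurationError("gamma1 must lie in (0, 1)")

    def sensitivity_matrix(self, config: WorldConfig) -> np.ndarray:
        if self.cover_sensitivity is None:
            # income gradient: the poorest country loses 5% of cover per
            # deg C, the richest gains 0.5% (poleward biome migration)
            u = np.arange(config.n_countries) / max(config.n_countries - 1, 1)
            s = -0.05 + 0.055 * u
            return np.repeat(s[:, None], config.n_biomes, axis=1)
        s = np.asarray(self.cover_sensitivity, dtype=float)
        if s.ndim == 0:
            return np.full((config.n_countries, config.n_biomes), float(s))
        if s.shape != (config.n_countries, config.n_biomes):
            raise ConfigurationError(
                "cover_sensitivity must be scalar or (n_countries, n_biomes)"
            )
        return s

    def value_weights(self, n_biomes: int) -> np.ndarray:
        if self.biome_value_weights is None:
            # later biomes carry more value per hectare, so perturbation
            # rankings have a known planted ordering; the scale keeps the
            # cover term a modest signal next to the log-noise sd, so the
            # stated noise level governs the elasticity regressions
            return (1.0 + np.arange(n_biomes, dtype=float)) / 10.0
        w = np.asarray(self.biome_value_weights, dtype=float)
        if w.shape != (n_biomes,):
            raise ConfigurationError("biome_value_weights must have length n_biomes")
        return w


@dataclass
class World:
    """A generated world: grid geometry, country mask and base-year fields."""

    config: WorldConfig
    truth: PlantedTruth
    mask: xr.DataArray  # (lat, lon) int country index, NO_COUNTRY elsewhere
    cover0: xr.DataArray  # (biome, lat, lon) base-year cover fraction
    carbon0: xr.DataArray  # (lat, lon) base-year vegetation carbon kg m^-2

    @property
    def biomes(self) -> list[str]:
        return list(self.cover0.biome.values)

    @property
    def countries(self) -> list[str]:
        return self.config.countries


def _rng(config_seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator stream derived from the master seed."""
    ss = np.random.SeedSequence([config_seed, abs(hash_stream(stream))])
    return np.random.default_rng(ss)


def hash_stream(name: str) -> int:
    # stable across processes (builtin hash is salted)
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def make_world(config: WorldConfig, truth: PlantedTruth | None = None) -> World:
    """Build the country mask and base-year cover / carbon grids.

    Countries are contiguous runs of cells in boustrophedon (snake) order over
    the vegetated rows, so they tile the grid.  Biome cover follows smooth
    Gaussian bands over latitude modulated by a seeded longitudinal texture;
    per-cell cover fractions are nonnegative and sum to at most 0.95.
    """
    truth = truth or PlantedTruth()
    config.validate()
    truth.validate()

    lat, lon = config.lat, config.lon
    n_lat, n_lon, n_b = config.n_lat, config.n_lon, config.n_biomes
    rng = _rng(config.seed, "world")

    # polar rows stay unassigned (non-vegetated) when the grid is tall enough
    vegetated_rows = np.abs(lat) <= 75.0
    if vegetated_rows.sum() < 2 or vegetated_rows.sum() * n_lon < config.n_countries:
        vegetated_rows = np.ones(n_lat, dtype=bool)

    mask = np.full((n_lat, n_lon), NO_COUNTRY, dtype=np.int32)
    rows = np.where(vegetated_rows)[0]
    order = []
    for j, i in enumerate(rows):
        cols = range(n_lon) if j % 2 == 0 else range(n_lon - 1, -1, -1)
        order.extend((i, c) for c in cols)
    splits = np.array_split(np.arange(len(order)), config.n_countries)
    for cid, idx in enumerate(splits):
        for k in idx:
            mask[order[k]] = cid

    # Gaussian latitude bands per biome
    centers = np.linspace(-60.0, 60.0, n_b) if n_b > 1 else np.array([0.0])
    width = max(15.0, 150.0 / max(n_b, 1))
    raw = np.exp(
        -(((lat[None, :, None] - centers[:, None, None]) / width) ** 2)
    ) * np.ones((1, 1, n_lon))
    raw *= 0.8 + 0.4 * rng.random((n_b, n_lat, n_lon))

    # trimodal vegetated-fraction target: equatorial peak plus two boreal bands
    target = 0.25 + 0.65 * np.maximum.reduce(
        [
            np.exp(-((lat / 25.0) ** 2)),
            np.exp(-(((lat - 55.0) / 15.0) ** 2)),
            np.exp(-(((lat + 55.0) / 15.0) ** 2)),
        ]
    )
    target = np.clip(target, 0.0, 0.95)
    total_raw = raw.sum(axis=0)
    cover = raw / np.maximum(total_raw, 1e-12) * target[None, :, None]
    cover[:, ~vegetated_rows, :] = 0.0

    total = cover.sum(axis=0)
    carbon = (0.5 + 8.0 * total) * np.exp(
        truth.carbon_noise_sd * 0.0 + 0.1 * rng.standard_normal((n_lat, n_lon))
    )
    carbon[~vegetated_rows, :] = 0.0

    coords = {"lat": lat, "lon": lon}
    cover_da = xr.DataArray(
        cover,
        dims=("biome", "lat", "lon"),
        coords={"biome": config.biomes, **coords},
        name="cover",
        attrs={"units": "fraction"},
    )
    carbon_da = xr.DataArray(
        carbon, dims=("lat", "lon"), coords=coords, name="carbon",
        attrs={"units": "kg m-2"},
    )
    mask_da = xr.DataArray(mask, dims=("lat", "lon"), coords=coords, name="country")
    return World(config=config, truth=truth, mask=mask_da, cover0=cover_da,
                 carbon0=carbon_da)


# ---------------------------------------------------------------------------
# Temperature paths and scenario runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperaturePath:
    """Global mean temperature anomaly (deg C) per calendar year, zero over
    the base period by construction."""

    series: pd.Series
    base_period: tuple[int, int] = BASE_PERIOD

    def anomaly(self, year: int) -> float:
        try:
            return float(self.series.loc[year])
        except KeyError as exc:
            raise InputError(f"no temperature anomaly for year {year}") from exc

    def anomalies(self, years) -> np.ndarray:
        return np.array([self.anomaly(int(y)) for y in years])

    def decade_mean(self, decade: int) -> float:
        years = [y for y in range(decade, decade + 10) if y in self.series.index]
        if not years:
            raise InputError(f"no temperature anomalies within decade {decade}s")
        return float(self.series.loc[years].mean())


def make_temperature_path(
    years=None,
    end_warming: float = 3.0,
    base_period: tuple[int, int] = BASE_PERIOD,
    end_year: int = 2100,
) -> TemperaturePath:
    """Linear anomaly ramp: zero through the end of the base period, reaching
    ``end_warming`` at ``end_year``."""
    if years is None:
        years = range(HORIZON[0], HORIZON[1] + 1)
    years = np.array(sorted(int(y) for y in years))
    y0 = base_period[1]
    dt = end_warming * np.clip((years - y0) / (end_year - y0), 0.0, None)
    return TemperaturePath(pd.Series(dt, index=years), base_period)


#: scenario-family end-of-century warming (deg C above the base period) and
#: per-climate-model scaling of that warming (decision: stylized but ordered
#: like typical low / middle / high forcing pathways)
RCP_WARMING = {"rcp26": 1.5, "rcp60": 3.0, "rcp85": 4.5}
GCM_FACTORS = {"gcm1": 0.85, "gcm2": 0.95, "gcm3": 1.05, "gcm4": 1.15}


def make_run_matrix(
    gcms=tuple(GCM_FACTORS),
    rcps=tuple(RCP_WARMING),
    years=None,
    base_period: tuple[int, int] = BASE_PERIOD,
) -> pd.DataFrame:
    """Scenario-run table: one row per (gcm, rcp) with its warming path.

    Returns a DataFrame with columns run_id, gcm, rcp and a ``path`` column
    holding each run's :class:`TemperaturePath`.
    """
    rows = []
    for gcm in gcms:
        for rcp in rcps:
            warm = RCP_WARMING.get(rcp, 3.0) * GCM_FACTORS.get(gcm, 1.0)
            path = make_temperature_path(years, warm, base_period)
            rows.append({"run_id": f"{gcm}_{rcp}", "gcm": gcm, "rcp": rcp,
                         "end_warming": warm, "path": path})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vegetation dynamics
# ---------------------------------------------------------------------------


def simulate_vegetation(
    world: World,
    path: TemperaturePath,
    truth: PlantedTruth | None = None,
    years=None,
    seed: int | None = None,
) -> xr.Dataset:
    """Linear-response vegetation dynamics around the base-year state.

    cover_b(cell, t) = clip(cover_b(cell, 0) * (1 + s_b(cell) * dT_t) + eps, 0, 1)
    carbon(cell, t)  = max(carbon(cell, 0) * (1 + s_c * dT_t) + eps, 0)

    With zero noise the response is exactly linear in the anomaly, which is
    what makes closed-form damage-slope oracles possible downstream.
    """
    truth = truth if truth is not None else world.truth
    if years is None:
        years = list(path.series.index)
    years = [int(y) for y in years]
    dts = path.anomalies(years)

    smat = truth.sensitivity_matrix(world.config)  # (country, biome)
    mask = world.mask.values
    n_b = world.config.n_biomes
    s_cell = np.zeros((n_b, *mask.shape))
    for cid in range(world.config.n_countries):
        sel = mask == cid
        for b in range(n_b):
            s_cell[b][sel] = smat[cid, b]

    rng = _rng(seed if seed is not None else world.config.seed, "vegetation")
    cover0 = world.cover0.values
    carbon0 = world.carbon0.values
    covers, carbons = [], []
    for dt in dts:
        c = cover0 * (1.0 + s_cell * dt)
        if truth.cover_noise_sd > 0:
            c = c + rng.normal(0.0, truth.cover_noise_sd, c.shape)
        covers.append(np.clip(c, 0.0, 1.0))
        k = carbon0 * (1.0 + truth.carbon_sensitivity * dt)
        if truth.carbon_noise_sd > 0:
            k = k + rng.normal(0.0, truth.carbon_noise_sd, k.shape)
        carbons.append(np.maximum(k, 0.0))

    coords = {"time": years, "biome": world.biomes,
              "lat": world.config.lat, "lon": world.config.lon}
    return xr.Dataset(
        {
            "cover": (("time", "biome", "lat", "lon"), np.stack(covers)),
            "carbon": (("time", "lat", "lon"), np.stack(carbons)),
        },
        coords=coords,
    )


# ---------------------------------------------------------------------------
# Valuation table
# ---------------------------------------------------------------------------


def make_vegs_table(
    world: World,
    truth: PlantedTruth | None = None,
    n_obs: int = 500,
    seed: int | None = None,
    benefit_types: tuple[str, ...] = ("non-market", "market"),
) -> pd.DataFrame:
    """Valuation records with the elasticities planted on the log scale.

    ``n_obs`` records are drawn per benefit type.  Each record samples a
    vegetated grid cell for its biome-cover profile (in percent) and draws
    site area, vegetation carbon and GDP per capita independently of the
    profile, so the three-regressor log-log elasticity regression downstream
    is unbiased by construction:

        log v = b0 + sum_b w_b cover_b/100
                + eta_area log(area) + eta_carbon log(carbon)
                + eta_income log(GDPpc) + N(0, noise_sd^2)

    Market records use the (null by default) market elasticities and halved
    biome weights.
    """
    truth = truth if truth is not None else world.truth
    if n_obs < 10:
        raise ConfigurationError("need at least 10 valuation records per type")
    rng = _rng(seed if seed is not None else world.config.seed, "vegs")

    cover = world.cover0.values  # (biome, lat, lon)
    veg_cells = np.argwhere(world.mask.values != NO_COUNTRY)
    w = truth.value_weights(world.config.n_biomes)

    frames = []
    for btype in benefit_types:
        pick = veg_cells[rng.integers(0, len(veg_cells), n_obs)]
        covers_pct = cover[:, pick[:, 0], pick[:, 1]].T * 100.0  # (n, biome)
        site_area = np.exp(rng.normal(8.0, 1.2, n_obs))
        carbon = np.exp(rng.normal(1.0, 0.7, n_obs))
        gdp_pc = np.exp(rng.normal(9.0, 1.0, n_obs))
        if btype == "market":
            e_a, e_c, e_i = truth.eta_area_market, truth.eta_carbon_market, 0.0
            weights = w / 2.0
        else:
            e_a, e_c, e_i = truth.eta_area, truth.eta_carbon, truth.eta_income
            weights = w
        logv = (
            np.log(200.0)
            + covers_pct @ weights / 100.0
            + e_a * np.log(site_area)
            + e_c * np.log(carbon)
            + e_i * np.log(gdp_pc)
        )
        if truth.noise_sd > 0:
            logv = logv + rng.normal(0.0, truth.noise_sd, n_obs)
        df = pd.DataFrame(covers_pct, columns=[f"cover_{b}" for b in world.biomes])
        df.insert(0, "benefit_type", btype)
        df["perc_covered"] = covers_pct.sum(axis=1) / 100.0
        df["site_area_ha"] = site_area
        df["carbon_kg_m2"] = carbon
        df["gdp_pc"] = gdp_pc
        df["value_per_ha_yr"] = np.exp(logv)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "record_id", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# Wealth accounts, trajectories and estimation panel
# ---------------------------------------------------------------------------


@dataclass
class Accounts:
    """Synthetic national accounts and socioeconomic inputs.

    accounts      one row per country: region, population, gdp_pc, GDP, H, K,
                  mN, nN, timber_share, savings_rate, tfp0, gamma1..3, b_r
    trajectories  (year, country): L, gdp_baseline, savings_rate, population
    panel         historical (year, country) panel of GDP, H, K, mN, nN, S
                  with the planted production structure, for elasticity
                  estimation
    base_year     the stock year
    """

    accounts: pd.DataFrame
    trajectories: pd.DataFrame
    panel: pd.DataFrame
    base_year: int


def make_accounts(
    world: World,
    truth: PlantedTruth | None = None,
    horizon: tuple[int, int] | None = None,
    base_year: int = 2018,
    n_panel_years: int = 20,
    seed: int | None = None,
) -> Accounts:
    """National accounts with a planted Cobb-Douglas production structure.

    Country GDP per capita spans ``truth.gdppc_range`` log-uniformly in
    country order; the natural-capital intensity (nN/GDP, mN/GDP) and the
    timber-rent share decline with income, reproducing the stylized fact that
    poorer economies depend more on natural capital.  Base-year GDP satisfies
    the production function exactly under the planted parameters (TFP is
    solved for and stored), and the historical panel embeds the planted
    region-specific environmental-good elasticities for recovery tests.
    """
    truth = truth if truth is not None else world.truth
    horizon = horizon or world.config.horizon_years
    cfg = world.config
    C = cfg.n_countries
    rng = _rng(seed if seed is not None else cfg.seed, "accounts")

    from .biome_accounting import cell_area_ha  # local to avoid cycle

    areas = cell_area_ha(cfg.lat, 180.0 / cfg.n_lat, 360.0 / cfg.n_lon)
    veg = (world.cover0.values.sum(axis=0) * areas[:, None])
    mask = world.mask.values
    veg_ha = np.array([veg[mask == cid].sum() for cid in range(C)])

    u = np.arange(C) / max(C - 1, 1)
    lo, hi = truth.gdppc_range
    gdp_pc = lo * (hi / lo) ** u

    rel = np.sqrt(hi / gdp_pc) / np.sqrt(hi / lo)  # 1 for poorest, -> 0 for richest
    population = np.maximum(veg_ha * (0.05 + 0.45 * rel), 1e6)
    gdp = gdp_pc * population

    nn = gdp * (0.05 + 0.55 * rel)
    mn = 0.25 * nn
    timber_share = 0.002 + 0.02 * rel
    # income-ordered region assignment: natural-capital dependence of
    # production (b) declines with income, so regions are ranked by b and
    # countries join them by GDP-per-capita quantile; tied incomes share a
    # region, keeping identical countries identical
    regions_by_b = sorted(truth.b_region, key=truth.b_region.get, reverse=True)
    rank = pd.Series(gdp_pc).rank(method="average").to_numpy()
    quant = (rank - 0.5) / C
    regions = [regions_by_b[min(len(regions_by_b) - 1,
                                int(q * len(regions_by_b)))] for q in quant]
    b_r = np.array([truth.b_region[r] for r in regions])
    gamma1 = np.full(C, truth.gamma1)
    gamma3 = timber_share
    gamma2 = 1.0 - gamma1 - gamma3
    if np.any(gamma2 <= 0):
        raise ConfigurationError("planted gamma2 <= 0: timber share too large")

    H = 2.5 * gdp
    K = 3.0 * gdp
    L = population
    S0 = nn.sum()
    tfp0 = gdp / (S0**b_r * L**gamma1 * K**gamma2 * mn**gamma3)

    accounts = pd.DataFrame(
        {
            "country": cfg.countries,
            "region": regions,
            "population": population,
            "gdp_pc": gdp_pc,
            "gdp": gdp,
            "human_capital": H,
            "manufactured_capital": K,
            "market_natcap": mn,
            "nonmarket_natcap": nn,
            "timber_share": timber_share,
            "savings_rate": SAVINGS_RATE,
            "gamma1": gamma1,
            "gamma2": gamma2,
            "gamma3": gamma3,
            "b_r": b_r,
            "tfp0": tfp0,
            "vegetated_ha": veg_ha,
        }
    ).set_index("country")

    # --- forward socioeconomic trajectories -------------------------------
    years = np.arange(horizon[0], horizon[1] + 1)
    t = years - base_year
    rows = []
    for i, c in enumerate(cfg.countries):
        pop_path = population[i] * (1.0 + 0.005) ** t
        g = 0.03 - 0.015 * u[i]  # convergence: poorer countries grow faster
        gdp_path = gdp[i] * (1.0 + g) ** t
        rows.append(
            pd.DataFrame(
                {
                    "year": years,
                    "country": c,
                    "labour": pop_path,
                    "population": pop_path,
                    "gdp_baseline": gdp_path,
                    "savings_rate": SAVINGS_RATE,
                }
            )
        )
    trajectories = pd.concat(rows, ignore_index=True)

    # --- historical estimation panel with planted production structure ----
    panel_years = np.arange(base_year - n_panel_years + 1, base_year + 1)
    tt = panel_years - base_year  # <= 0
    # nN paths: common global growth so S varies over time (identifying b)
    nn_path = nn[None, :] * np.exp(0.02 * tt)[:, None]
    drift = np.exp(0.025 * tt)[:, None]
    shocks = lambda: np.exp(rng.normal(0.0, 0.05, (len(panel_years), C)))  # noqa: E731
    H_path = H[None, :] * drift * shocks()
    K_path = K[None, :] * drift * shocks()
    mn_path = mn[None, :] * drift * shocks()
    # base year pinned to the accounts row exactly
    H_path[-1], K_path[-1], mn_path[-1], nn_path[-1] = H, K, mn, nn
    S_path = nn_path.sum(axis=1)
    # the panel's data-generating process matches the estimation
    # specification (a single market-natural-capital elasticity); the
    # country effect a_c absorbs the base-year level difference against the
    # country-specific production parameters used in the simulation
    g3p = float(np.mean(gamma3))
    g2p = 1.0 - truth.gamma1 - g3p
    a_c = (
        np.log(gdp)
        - b_r * np.log(S0)
        - truth.gamma1 * np.log(H)
        - g2p * np.log(K)
        - g3p * np.log(mn)
    )
    log_gdp = (
        a_c[None, :]
        + b_r[None, :] * np.log(S_path)[:, None]
        + truth.gamma1 * np.log(H_path)
        + g2p * np.log(K_path)
        + g3p * np.log(mn_path)
    )
    if truth.gdp_noise_sd > 0:
        eps = rng.normal(0.0, truth.gdp_noise_sd, log_gdp.shape)
        eps[-1] = 0.0  # keep the base year exact
        log_gdp = log_gdp + eps
    panel = pd.DataFrame(
        {
            "year": np.repeat(panel_years, C),
            "country": np.tile(cfg.countries, len(panel_years)),
            "region": np.tile(regions, len(panel_years)),
            "gdp": np.exp(log_gdp).ravel(),
            "human_capital": H_path.ravel(),
            "manufactured_capital": K_path.ravel(),
            "market_natcap": mn_path.ravel(),
            "nonmarket_natcap": nn_path.ravel(),
            "global_nonmarket": np.repeat(S_path, C),
        }
    )
    return Accounts(accounts=accounts, trajectories=trajectories, panel=panel,
                    base_year=base_year)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------


def save_world(world: World, directory) -> dict[str, str]:
    """Write the world as NetCDF grids plus a YAML config; returns paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    grid = xr.Dataset({"cover": world.cover0, "carbon": world.carbon0})
    grid_path = directory / "base_grid.nc"
    grid.to_netcdf(grid_path)
    paths["base_grid"] = str(grid_path)

    mask_path = directory / "country_mask.nc"
    world.mask.to_dataset(name="country").to_netcdf(mask_path)
    paths["country_mask"] = str(mask_path)

    cfg_path = directory / "world_config.yaml"
    cfg = {
        "n_lat": world.config.n_lat,
        "n_lon": world.config.n_lon,
        "n_countries": world.config.n_countries,
        "n_biomes": world.config.n_biomes,
        "seed": world.config.seed,
        "horizon_years": list(world.config.horizon_years),
        "base_period": list(world.config.base_period),
    }
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    paths["world_config"] = str(cfg_path)
    logger.info("synthetic_data wrote %d artifacts to %s", len(paths), directory)
    return paths


def with_noiseless(truth: PlantedTruth) -> PlantedTruth:
    """Copy of the planted truth with every noise source switched off."""
    return replace(truth, noise_sd=0.0, cover_noise_sd=0.0, carbon_noise_sd=0.0,
                   gdp_noise_sd=0.0)
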