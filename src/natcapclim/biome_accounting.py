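"""Country-by-biome accounting of gridded vegetation fields.

Converts fractional biome cover and vegetation carbon on a regular
latitude-longitude grid into country-level quantities: hectares per biome
(a_{t,c,b}), total vegetated hectares (A_{t,c}), the fraction of country
territory that is vegetated, the cover-weighted mean vegetation carbon per
vegetated hectare, and the percentage changes of area and carbon against a
baseline year.  Cells are attributed to countries whole (no areal splitting
of border cells); typologies map model-native plant-functional-type names to
the biome classes used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import EARTH_RADIUS_M, logger, log_decision
from .synthetic_data import NO_COUNTRY


class GridMismatchError(ValueError):
    """Grid and mask do not share the same geometry."""


class TypologyError(KeyError):
    """A plant functional type has no biome mapping."""


class UndefinedChangeError(ValueError):
    """Percentage change requested against a zero baseline."""


# ---------------------------------------------------------------------------
# Typologies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiomeTypology:
    """Total mapping from model-native PFT names to biome classes.

    Non-vegetated classes (mapped to ``None``) carry zero value and are
    dropped from the accounting.
    """

    name: str = "native"
    mapping: dict[str, str | None] = field(default_factory=dict)

    def biome_of(self, pft: str) -> str | None:
        if not self.mapping:
            return pft  # identity typology
        try:
            return self.mapping[pft]
        except KeyError as exc:
            raise TypologyError(f"PFT {pft!r} missing from typology "
                                f"{self.name!r}") from exc

    def apply(self, cover: xr.DataArray) -> xr.DataArray:
        """Sum PFT covers into biome classes along the ``biome`` dimension."""
        if not self.mapping:
            return cover
        groups: dict[str, list[str]] = {}
        for pft in map(str, cover.biome.values):
            target = self.biome_of(pft)
            if target is not None:
                groups.setdefault(target, []).append(pft)
        out = xr.concat(
            [cover.sel(biome=pfts).sum("biome", keep_attrs=True).assign_coords(biome=b)
             for b, pfts in sorted(groups.items())],
            dim="biome",
        )
        return out


# ---------------------------------------------------------------------------
# Cell geometry
# ---------------------------------------------------------------------------


def cell_area_ha(lat_centers, dlat_deg: float, dlon_deg: float) -> np.ndarray:
    """Area in hectares of each grid cell as a function of latitude.

    Spherical geometry: area = R^2 * dlon * (sin(top) - sin(bottom)); cells
    whose edges cross a pole are clipped to it (with a logged warning).  A
    0.5-degree cell at the equator is about 3.09e5 ha.
    """
    lat = np.asarray(lat_centers, dtype=float)
    half = dlat_deg / 2.0
    top = lat + half
    bottom = lat - half
    if np.any(top > 90.0) or np.any(bottom < -90.0):
        logger.warning("cells crossing a pole clipped to +/-90 degrees")
        top = np.clip(top, -90.0, 90.0)
        bottom = np.clip(bottom, -90.0, 90.0)
    dlon = np.deg2rad(dlon_deg)
    area_m2 = EARTH_RADIUS_M**2 * dlon * (np.sin(np.deg2rad(top)) - np.sin(np.deg2rad(bottom)))
    return area_m2 / 1e4


def _grid_areas(da: xr.DataArray) -> np.ndarray:
    lat = da.lat.values
    lon = da.lon.values
    dlat = float(np.diff(lat).mean()) if lat.size > 1 else 180.0
    dlon = float(np.diff(lon).mean()) if lon.size > 1 else 360.0
    return cell_area_ha(lat, dlat, dlon)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class CountryBiomeAreas:
    """Aggregated country-level vegetation accounts for one year.

    by_biome    (country, biome) -> hectares
    by_country  country -> total_veg_ha, territory_ha, perc_covered,
                mean_carbon (cover-weighted kg m^-2 over vegetated area)
    """

    year: int
    by_biome: pd.DataFrame
    by_country: pd.DataFrame

    def area_matrix(self) -> pd.DataFrame:
        return self.by_biome.pivot(index="country", columns="biome",
                                   values="hectares")


def aggregate_to_country(
    cover: xr.DataArray,
    carbon: xr.DataArray,
    mask: xr.DataArray,
    typology: BiomeTypology | None = None,
    year: int | None = None,
    country_names: list[str] | None = None,
) -> CountryBiomeAreas:
    """Aggregate a single-year grid to country-by-biome hectares.

    a_{c,b} = sum over the country's cells of cover_b * cell_area.  The mean
    carbon is weighted by vegetated area (total cover times cell area).
    """
    if cover.lat.size != mask.lat.size or cover.lon.size != mask.lon.size or \
            not np.allclose(cover.lat.values, mask.lat.values) or \
            not np.allclose(cover.lon.values, mask.lon.values):
        raise GridMismatchError("cover grid and country mask geometries differ")
    if "time" in cover.dims:
        if year is None:
            raise ValueError("year required for a multi-year grid")
        cover = cover.sel(time=year)
        carbon = carbon.sel(time=year)
    typology = typology or BiomeTypology()
    cover = typology.apply(cover)

    areas = _grid_areas(cover)[:, None] * np.ones((1, cover.lon.size))
    m = mask.values
    ids = sorted(int(c) for c in np.unique(m) if c != NO_COUNTRY)
    if country_names is None:
        country_names = [f"C{int(c):02d}" for c in ids]
    biomes = [str(b) for b in cover.biome.values]
    cov = cover.values  # (biome, lat, lon)
    car = carbon.values
    vegfrac = cov.sum(axis=0)

    rows, crows = [], []
    for cid, cname in zip(ids, country_names):
        sel = m == cid
        if not sel.any():
            raise ValueError(f"country {cname} has no cells in the mask")
        cell_a = areas[sel]
        territory = cell_a.sum()
        ha_b = (cov[:, sel] * cell_a[None, :]).sum(axis=1)
        veg_ha = ha_b.sum()
        vw = vegfrac[sel] * cell_a
        mean_carbon = float((car[sel] * vw).sum() / vw.sum()) if vw.sum() > 0 else 0.0
        for b, ha in zip(biomes, ha_b):
            rows.append({"country": cname, "biome": b, "hectares": float(ha)})
        crows.append(
            {
                "country": cname,
                "territory_ha": float(territory),
                "total_veg_ha": float(veg_ha),
                "perc_covered": float(veg_ha / territory) if territory > 0 else 0.0,
                "mean_carbon": mean_carbon,
            }
        )
    yr = int(year) if year is not None else -1
    return CountryBiomeAreas(
        year=yr,
        by_biome=pd.DataFrame(rows).assign(year=yr),
        by_country=pd.DataFrame(crows).set_index("country").assign(year=yr),
    )


def aggregate_series(
    ds: xr.Dataset,
    mask: xr.DataArray,
    typology: BiomeTypology | None = None,
    country_names: list[str] | None = None,
) -> dict[int, CountryBiomeAreas]:
    """Aggregate every year of a (time, biome, lat, lon) dataset."""
    return {
        int(y): aggregate_to_country(ds["cover"], ds["carbon"], mask, typology,
                                     year=int(y), country_names=country_names)
        for y in ds.time.values
    }


# ---------------------------------------------------------------------------
# Percentage changes
# ---------------------------------------------------------------------------


def pct_changes(current: CountryBiomeAreas, base: CountryBiomeAreas) -> pd.DataFrame:
    """Percentage change of total vegetated area (a_dot) and of mean carbon
    (c_dot) per country relative to the baseline year.

    Countries with a zero baseline are excluded and logged rather than
    producing undefined changes.
    """
    out = []
    for country in base.by_country.index:
        a0 = base.by_country.loc[country, "total_veg_ha"]
        c0 = base.by_country.loc[country, "mean_carbon"]
        if a0 <= 0 or c0 <= 0:
            log_decision("biome_accounting", country, "excluded_zero_baseline",
                         A0=a0, C0=c0)
            continue
        a1 = current.by_country.loc[country, "total_veg_ha"]
        c1 = current.by_country.loc[country, "mean_carbon"]
        out.append(
            {
                "country": country,
                "a_dot": 100.0 * (a1 / a0 - 1.0),
                "c_dot": 100.0 * (c1 / c0 - 1.0),
            }
        )
    if not out:
        raise UndefinedChangeError("no country has a positive baseline")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_grid(path, var_map: dict[str, str] | None = None) -> xr.Dataset:
    """Read a NetCDF vegetation grid; ``var_map`` renames model-native
    variable names onto the package's (cover, carbon) convention."""
    ds = xr.open_dataset(path)
    if var_map:
        ds = ds.rename(var_map)
    _validate_grid(ds)
    return ds


def read_mask(path) -> xr.DataArray:
    return xr.open_dataset(path)["country"]


def _validate_grid(ds: xr.Dataset) -> None:
    cov = ds["cover"]
    if float(cov.min()) < 0:
        raise ValueError("negative cover fractions in grid")
    if float(cov.sum("biome").max()) > 1.0 + 1e-6:
        raise ValueError("per-cell cover fractions sum above 1")
    if "carbon" in ds and float(ds["carbon"].min()) < 0:
        raise ValueError("negative vegetation carbon in grid")


def write_areas(aggregates: dict[int, CountryBiomeAreas], path) -> str:
    """Write the tidy (year, country, biome, hectares) table as CSV."""
    tidy = pd.concat([a.by_biome for a in aggregates.values()], ignore_index=True)
    tidy = tidy[["year", "country", "biome", "hectares"]]
    tidy.to_csv(path, index=False)
    return str(path)
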