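"""Projecting natural-capital trajectories under scenario runs.

Non-market natural capital in year t is the perpetuity value of the biome
areas times their (2018-vintage) per-hectare values, adjusted by a country
multiplier that responds to the percentage change of total vegetated area
(a_dot, elasticity -0.103) and of mean vegetation carbon (c_dot, elasticity
0.282); both changes are clamped to configurable caps before the multiplier
is evaluated, and the multiplier is floored at zero.  Market natural capital
responds to area only (market elasticities are indistinguishable from zero).
Trajectories are then normalized by their base-year values to give the
relative changes that feed the damage regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CAP_AREA_PCT,
    CAP_CARBON_PCT,
    DISCOUNT_RATE,
    ETA_AREA,
    ETA_CARBON,
    log_decision,
)


def adjust_multiplier(
    a_dot: float,
    c_dot: float,
    eta_area: float = ETA_AREA,
    eta_carbon: float = ETA_CARBON,
    cap_a: float = CAP_AREA_PCT,
    cap_c: float = CAP_CARBON_PCT,
) -> float:
    """Per-hectare value multiplier 1 + (eta_c * c_dot + eta_a * a_dot)/100.

    a_dot and c_dot are percentage changes and are clamped to [-cap, +cap]
    first; the result is floored at 0 (values cannot turn negative).
    """
    if cap_a <= 0 or cap_c <= 0:
        raise ValueError("caps must be positive")
    a = float(np.clip(a_dot, -cap_a, cap_a))
    c = float(np.clip(c_dot, -cap_c, cap_c))
    return max(0.0, 1.0 + (eta_carbon * c + eta_area * a) / 100.0)


def project_nonmarket(
    areas_t: pd.Series,
    es: pd.Series,
    a_dot: float,
    c_dot: float,
    r: float = DISCOUNT_RATE,
    eta_area: float = ETA_AREA,
    eta_carbon: float = ETA_CARBON,
    cap_a: float = CAP_AREA_PCT,
    cap_c: float = CAP_CARBON_PCT,
) -> float:
    """nN_t = sum_b a_{t,b} es_b * multiplier(a_dot, c_dot) / r, floored at 0.

    The multiplier applies uniformly across the country's biomes; per-hectare
    values are the fixed 2018 estimates.
    """
    missing = [b for b in areas_t.index if b not in es.index]
    if missing:
        raise KeyError(f"missing per-hectare values for biomes {missing}")
    mult = adjust_multiplier(a_dot, c_dot, eta_area, eta_carbon, cap_a, cap_c)
    return max(0.0, float((areas_t * es.loc[areas_t.index]).sum()) * mult / r)


def project_market(
    areas_t: pd.Series,
    x: pd.Series,
    r_hat: float,
    r: float = DISCOUNT_RATE,
) -> float:
    """mN_t = sum_b a_{t,b} x_b R_hat / r — area response only."""
    missing = [b for b in areas_t.index if b not in x.index]
    if missing:
        raise KeyError(f"missing market scaling factors for biomes {missing}")
    return max(0.0, float((areas_t * x.loc[areas_t.index]).sum()) * r_hat / r)


def project_run(
    aggregates: dict,  # year -> CountryBiomeAreas (incl. the base year)
    per_hectare: pd.DataFrame,
    base_areas,  # CountryBiomeAreas at the base year
    r: float = DISCOUNT_RATE,
    eta_area: float = ETA_AREA,
    eta_carbon: float = ETA_CARBON,
    cap_a: float = CAP_AREA_PCT,
    cap_c: float = CAP_CARBON_PCT,
    typology: str = "native",
) -> pd.DataFrame:
    """Natural-capital trajectory for one scenario run.

    Returns a tidy frame (year, country, nonmarket_natcap, market_natcap).
    Percentage changes of area and carbon are computed against the base-year
    aggregation; market per-hectare values are used directly (equivalent to
    x_b * R_hat of the reference biome, since both come from the same
    apportionment).
    """
    from .biome_accounting import pct_changes

    ph = per_hectare[per_hectare["typology"] == typology]
    es_n = ph[ph.benefit_type == "non-market"].pivot(
        index="country", columns="biome", values="value_per_ha_yr")
    es_m = ph[ph.benefit_type == "market"].pivot(
        index="country", columns="biome", values="value_per_ha_yr")

    rows = []
    for year, agg in aggregates.items():
        changes = pct_changes(agg, base_areas).set_index("country")
        amat = agg.area_matrix()
        for country in amat.index:
            if country not in changes.index or country not in es_n.index:
                continue
            a_dot = float(changes.loc[country, "a_dot"])
            c_dot = float(changes.loc[country, "c_dot"])
            nn = project_nonmarket(amat.loc[country], es_n.loc[country],
                                   a_dot, c_dot, r, eta_area, eta_carbon,
                                   cap_a, cap_c)
            mn = project_market(amat.loc[country],
                                es_m.loc[country] / es_m.loc[country].max()
                                if es_m.loc[country].max() > 0
                                else es_m.loc[country],
                                float(es_m.loc[country].max()), r)
            rows.append({"year": int(year), "country": country,
                         "nonmarket_natcap": nn, "market_natcap": mn,
                         "a_dot": a_dot, "c_dot": c_dot})
    return pd.DataFrame(rows)


def normalize_changes(traj: pd.DataFrame, base_year: int) -> pd.DataFrame:
    """Relative changes d_nN_hat = nN_t / nN_0 - 1 (and the market analogue).

    Countries with a zero base-year value are excluded with a log entry.
    """
    base = traj[traj.year == base_year].set_index("country")
    if base.empty:
        raise ValueError(f"base year {base_year} missing from trajectory")
    rows = []
    for _, rec in traj.iterrows():
        c = rec["country"]
        nn0 = base.loc[c, "nonmarket_natcap"]
        mn0 = base.loc[c, "market_natcap"]
        if nn0 <= 0 or mn0 <= 0:
            log_decision("projection", c, "excluded_zero_base", nn0=nn0, mn0=mn0)
            continue
        rows.append(
            {
                "year": int(rec["year"]),
                "country": c,
                "d_nN_hat": rec["nonmarket_natcap"] / nn0 - 1.0,
                "d_mN_hat": rec["market_natcap"] / mn0 - 1.0,
            }
        )
    return pd.DataFrame(rows)
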