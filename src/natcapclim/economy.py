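"""Cobb-Douglas economy with natural capital and damage feedback.

Production per country is

    GDP = TFP * S^b_r * L^g1 * K^g2 * mN^g3,   g1 + g2 + g3 = 1,

where S is the GLOBAL stock of non-market natural capital entering as an
environmental public good with a region-specific elasticity b_r, and mN is
the country's market natural capital.  The module estimates (b_r, g1) from a
GDP-weighted log-linear panel regression with country fixed effects, assigns
g3 from timber-rent shares of GDP (g2 by constant returns), calibrates TFP so
a baseline with natural capital fixed at its base-year level reproduces an
exogenous GDP path exactly, and then simulates damaged runs in which the
natural-capital stocks respond linearly to warming through the fitted damage
coefficients.  Impact summaries compare damaged and baseline runs and
measure how losses distribute across the income ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    DELTA_DEPRECIATION,
    DISCOUNT_RATE,
    ETA_INCOME,
    HORIZON,
    STEP_YEARS,
    log_decision,
    logger,
)


class UnidentifiedError(ValueError):
    """A production elasticity cannot be identified from the panel."""


# ---------------------------------------------------------------------------
# Elasticity estimation (panel regression)
# ---------------------------------------------------------------------------


@dataclass
class ElasticityFit:
    """Estimated production elasticities.

    b_region maps each macro region to its elasticity of the global
    environmental good; gamma1/2/3 are the common labour (human capital),
    manufactured-capital and market-natural-capital elasticities.
    """

    b_region: dict[str, float]
    gamma1: float
    gamma2: float
    gamma3: float
    se: dict[str, float]

    def b_for(self, region: str) -> float:
        return self.b_region[region]


def calibrate_elasticities(
    panel: pd.DataFrame,
    weight_col: str = "gdp",
    cluster_by_region: bool = True,
) -> ElasticityFit:
    """GDP-weighted panel regression of log GDP on region-interacted log S,
    log human capital, log manufactured capital and log market natural
    capital, with country fixed effects and year effects.

    Because S is a single global series, a full set of year dummies would be
    collinear with the region-interacted log S block (their sum is exactly
    log S_t, a pure function of the year); the year effects therefore omit
    two reference years — one for the usual level redundancy against the
    country dummies and one to break that collinearity — and the design rank
    is checked.  Standard errors are clustered by macro region by default.
    """
    need = {"year", "country", "region", "gdp", "human_capital",
            "manufactured_capital", "market_natcap", "global_nonmarket"}
    missing = need - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns {sorted(missing)}")
    if panel["country"].nunique() < 2 or panel["year"].nunique() < 3:
        raise ValueError("panel needs >= 2 countries and >= 3 years")
    logS = np.log(panel["global_nonmarket"].to_numpy())
    if np.unique(np.round(logS, 12)).size < 2:
        raise UnidentifiedError("global non-market natural capital is constant "
                                "over time; b cannot be identified")

    regions = sorted(panel["region"].unique())
    countries = sorted(panel["country"].unique())
    years = sorted(panel["year"].unique())

    cols, names = [], []
    for reg in regions:
        cols.append(((panel["region"] == reg).to_numpy(float)) * logS)
        names.append(f"b[{reg}]")
    for col, nm in (("human_capital", "g1"), ("manufactured_capital", "g2"),
                    ("market_natcap", "g3")):
        cols.append(np.log(panel[col].to_numpy()))
        names.append(nm)
    for c in countries:
        cols.append((panel["country"] == c).to_numpy(float))
        names.append(f"fe_c[{c}]")
    for y in years[2:]:
        cols.append((panel["year"] == y).to_numpy(float))
        names.append(f"fe_t[{y}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnidentifiedError("rank-deficient panel design")

    y = np.log(panel["gdp"].to_numpy())
    w = panel[weight_col].to_numpy()
    model = sm.WLS(y, X, weights=w)
    if cluster_by_region and len(regions) >= 2:
        codes = pd.Categorical(panel["region"]).codes
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": codes})
    else:
        fit = model.fit()

    params = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    return ElasticityFit(
        b_region={reg: float(params[f"b[{reg}]"]) for reg in regions},
        gamma1=float(params["g1"]),
        gamma2=float(params["g2"]),
        gamma3=float(params["g3"]),
        se={k: float(v) for k, v in ses.items()
            if not k.startswith("fe_")},
    )


def assign_country_elasticities(timber_share: float, gamma1: float
                                ) -> tuple[float, float]:
    """(gamma3, gamma2) from the timber-rent share of GDP under constant
    returns to scale: gamma3 = share, gamma2 = 1 - gamma1 - gamma3."""
    if not 0.0 <= timber_share < 1.0 - gamma1:
        raise ValueError(
            f"timber share {timber_share} incompatible with gamma1={gamma1}")
    gamma3 = float(timber_share)
    gamma2 = 1.0 - gamma1 - gamma3
    if gamma2 <= 0:
        raise ValueError("gamma2 <= 0")
    return gamma3, gamma2


# ---------------------------------------------------------------------------
# Production and capital accumulation
# ---------------------------------------------------------------------------


def gdp(tfp, S, L, K, mN, gamma1, gamma2, gamma3, b):
    """Cobb-Douglas output; vectorized over countries.

    Zero inputs are allowed only where the exponent is zero (then the factor
    contributes 1 by convention 0^0 = 1); a zero input with a positive
    exponent yields zero output with a warning; negative inputs are errors.
    """
    factors = [(S, b), (L, gamma1), (K, gamma2), (mN, gamma3)]
    out = np.asarray(tfp, dtype=float).copy()
    for val, exp in factors:
        v = np.asarray(val, dtype=float)
        e = np.asarray(exp, dtype=float)
        if np.any(v < 0):
            raise ValueError("negative production input")
        zero_pos = (v == 0) & (e > 0)
        if np.any(zero_pos):
            logger.warning("zero production input with positive exponent: "
                           "output forced to zero")
        with np.errstate(divide="ignore"):
            term = np.where(v > 0, v, 1.0) ** e
        term = np.where(zero_pos, 0.0, term)
        out = out * term
    return out if out.ndim else float(out)


def step_capital(K, gdp_flow, s, delta: float = DELTA_DEPRECIATION,
                 step_years: int = STEP_YEARS):
    """K' = K (1 - delta)^step + step * s * GDP (gross-savings accumulation)."""
    K = np.asarray(K, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(K < 0):
        raise ValueError("negative capital stock")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("savings rate outside [0, 1]")
    out = K * (1.0 - delta) ** step_years + step_years * s * np.asarray(gdp_flow)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# TFP calibration
# ---------------------------------------------------------------------------


def calibrate_tfp(
    gdp_target: pd.DataFrame,  # (year x country) wide
    labour: pd.DataFrame,      # (year x country) wide
    k0: pd.Series,
    mn0: pd.Series,
    nn0: pd.Series,
    params: pd.DataFrame,      # per-country gamma1..3, b_r
    savings: float | pd.DataFrame = 0.25,
    delta: float = DELTA_DEPRECIATION,
    step_years: int = STEP_YEARS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Solve TFP_t so the baseline (natural capital frozen at base-year
    levels) reproduces the target GDP path exactly.

    Forward recursion: at each step the capital stock implied by past target
    GDP is computed, then TFP = target / (S^b L^g1 K^g2 mN^g3).  Returns
    (tfp, k_path) as (year x country) frames.  Re-simulating the baseline
    with this TFP reproduces the target to machine precision.
    """
    countries = list(gdp_target.columns)
    years = list(gdp_target.index)
    if (gdp_target <= 0).any().any():
        raise ValueError("baseline GDP path must be strictly positive")
    S0 = float(nn0.sum())
    g1 = params.loc[countries, "gamma1"].to_numpy()
    g2 = params.loc[countries, "gamma2"].to_numpy()
    g3 = params.loc[countries, "gamma3"].to_numpy()
    b = params.loc[countries, "b_r"].to_numpy()
    mn = mn0.loc[countries].to_numpy()
    if np.any(mn <= 0) or S0 <= 0 or np.any(k0.loc[countries].to_numpy() <= 0):
        raise ValueError("zero or negative factor in TFP calibration")

    K = k0.loc[countries].to_numpy(dtype=float)
    tfp_rows, k_rows = [], []
    for year in years:
        L = labour.loc[year, countries].to_numpy(dtype=float)
        target = gdp_target.loc[year, countries].to_numpy(dtype=float)
        denom = gdp(np.ones_like(K), S0, L, K, mn, g1, g2, g3, b)
        if np.any(denom <= 0):
            raise ValueError("zero factor product in TFP calibration")
        tfp_rows.append(target / denom)
        k_rows.append(K.copy())
        s = savings if np.isscalar(savings) else savings.loc[year, countries].to_numpy()
        K = step_capital(K, target, s, delta, step_years)
    tfp = pd.DataFrame(tfp_rows, index=years, columns=countries)
    k_path = pd.DataFrame(k_rows, index=years, columns=countries)
    return tfp, k_path


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def simulate(
    accounts: pd.DataFrame,     # per-country stocks and parameters
    tfp: pd.DataFrame,          # (year x country), from calibrate_tfp
    labour: pd.DataFrame,       # (year x country)
    theta: pd.DataFrame | None = None,  # damage coefficients (country, target)
    temp_path=None,
    mode: str = "baseline",
    savings: float | pd.DataFrame = 0.25,
    delta: float = DELTA_DEPRECIATION,
    step_years: int = STEP_YEARS,
    r: float = DISCOUNT_RATE,
    eta_income: float = ETA_INCOME,
) -> pd.DataFrame:
    """Run the economy forward in 5-year steps.

    Baseline mode freezes nN and mN at their base-year values (theta = 0);
    damaged mode scales them by max(0, 1 + theta * dT_t).  The global
    environmental good S_t is the sum of country nN_t; capital accumulates
    out of the run's own GDP, so damages feed back through savings.  The
    ecosystem-service flow is ES = nN * r * (1 + eta_income * %dGDPpc), with
    the GDP-per-capita change measured against the run's own first year.

    Returns a tidy frame (year, country, labour, capital, tfp, market_natcap,
    nonmarket_natcap, global_nonmarket, gdp, es_flow, run).
    """
    countries = list(tfp.columns)
    years = list(tfp.index)
    nn0 = accounts.loc[countries, "nonmarket_natcap"].to_numpy(dtype=float)
    mn0 = accounts.loc[countries, "market_natcap"].to_numpy(dtype=float)
    g1 = accounts.loc[countries, "gamma1"].to_numpy()
    g2 = accounts.loc[countries, "gamma2"].to_numpy()
    g3 = accounts.loc[countries, "gamma3"].to_numpy()
    b = accounts.loc[countries, "b_r"].to_numpy()

    if mode == "damaged":
        if theta is None or temp_path is None:
            raise ValueError("damaged mode needs damage coefficients and a "
                             "temperature path")
        th = theta.pivot(index="country", columns="target", values="theta")
        th_n = th.loc[countries, "nN"].to_numpy(dtype=float)
        th_m = th.loc[countries, "mN"].to_numpy(dtype=float)
    else:
        th_n = np.zeros(len(countries))
        th_m = np.zeros(len(countries))

    K = (3.0 * accounts.loc[countries, "gdp"]).to_numpy(dtype=float) \
        if "manufactured_capital" not in accounts.columns \
        else accounts.loc[countries, "manufactured_capital"].to_numpy(dtype=float)

    base_gdppc = None
    rows = []
    for year in years:
        dt = temp_path.anomaly(year) if temp_path is not None else 0.0
        nn_t = np.maximum(0.0, nn0 * (1.0 + th_n * dt))
        mn_t = np.maximum(0.0, mn0 * (1.0 + th_m * dt))
        S_t = float(nn_t.sum())
        L = labour.loc[year, countries].to_numpy(dtype=float)
        tfp_t = tfp.loc[year, countries].to_numpy(dtype=float)
        gdp_t = gdp(tfp_t, S_t, L, K, mn_t, g1, g2, g3, b)
        gdppc = gdp_t / L
        if base_gdppc is None:
            base_gdppc = gdppc.copy()
        pct_dgdppc = np.where(base_gdppc > 0,
                              100.0 * (gdppc / np.where(base_gdppc > 0,
                                                        base_gdppc, 1.0) - 1.0),
                              0.0)
        es = es_flow(nn_t, r, pct_dgdppc, eta_income)
        for i, c in enumerate(countries):
            rows.append(
                {
                    "year": int(year), "country": c, "labour": L[i],
                    "capital": K[i], "tfp": tfp_t[i],
                    "market_natcap": mn_t[i], "nonmarket_natcap": nn_t[i],
                    "global_nonmarket": S_t, "gdp": gdp_t[i],
                    "es_flow": es[i], "run": mode,
                }
            )
        s = savings if np.isscalar(savings) else savings.loc[year, countries].to_numpy()
        K = step_capital(K, gdp_t, s, delta, step_years)
    return pd.DataFrame(rows)


def es_flow(nN, r: float = DISCOUNT_RATE, pct_dgdppc=0.0,
            eta_income: float = ETA_INCOME):
    """Annual non-market benefit flow: ES = nN * r * (1 + eta * %dGDPpc)."""
    nN = np.asarray(nN, dtype=float)
    if np.any(nN < 0):
        raise ValueError("negative non-market natural capital")
    out = nN * r * (1.0 + eta_income * np.asarray(pct_dgdppc, dtype=float))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Impact summaries and distribution
# ---------------------------------------------------------------------------


@dataclass
class ImpactSummary:
    """Damaged-vs-baseline impacts.

    by_country        (year, country): pct_gdp, pct_es, gdp_loss (currency,
                      positive = loss)
    global_pct_gdp    population-weighted mean %dGDP at the evaluation year
    global_pct_es     population-weighted mean %dES at the evaluation year
    eval_year         the year of the global means
    """

    by_country: pd.DataFrame
    global_pct_gdp: float
    global_pct_es: float
    eval_year: int


def impacts(
    baseline: pd.DataFrame,
    damaged: pd.DataFrame,
    population: pd.DataFrame,  # (year x country)
    eval_year: int = HORIZON[1],
) -> ImpactSummary:
    """Percentage impacts per country-year and population-weighted global
    means in the evaluation year."""
    key = ["year", "country"]
    merged = baseline.merge(damaged, on=key, suffixes=("_base", "_dam"))
    rows = []
    for _, rec in merged.iterrows():
        if rec["gdp_base"] <= 0:
            log_decision("economy", rec["country"], "excluded_zero_gdp",
                         year=rec["year"])
            continue
        rows.append(
            {
                "year": int(rec["year"]),
                "country": rec["country"],
                "pct_gdp": 100.0 * (rec["gdp_dam"] - rec["gdp_base"]) / rec["gdp_base"],
                "pct_es": 100.0 * (rec["es_flow_dam"] - rec["es_flow_base"])
                / rec["es_flow_base"] if rec["es_flow_base"] > 0 else np.nan,
                "gdp_loss": rec["gdp_base"] - rec["gdp_dam"],
            }
        )
    by_country = pd.DataFrame(rows)
    at = by_country[by_country.year == eval_year].set_index("country")
    pop = population.loc[eval_year, at.index].to_numpy(dtype=float)
    w = pop / pop.sum()
    return ImpactSummary(
        by_country=by_country,
        global_pct_gdp=float((w * at["pct_gdp"].to_numpy()).sum()),
        global_pct_es=float(np.nansum(w * at["pct_es"].to_numpy())),
        eval_year=eval_year,
    )


def damage_distribution(
    losses: pd.Series,       # currency loss per country (positive = loss)
    gdp_pc: pd.Series,       # baseline GDP per capita used for ranking
    population: pd.Series,
    bottom_frac: float = 0.5,
    top_frac: float = 0.1,
) -> dict:
    """Share of total losses borne by the poorest ``bottom_frac`` and the
    richest ``top_frac`` of the population.

    Countries are ranked by GDP per capita; group membership is by whole
    country, adding countries while the cumulative population BEFORE them is
    below the threshold.  Gains (negative losses) are excluded from both the
    numerator and the denominator and reported separately.
    """
    idx = losses.index
    loss_only = losses.clip(lower=0.0)
    gains = (-losses).clip(lower=0.0)
    total = float(loss_only.sum())
    if total <= 0:
        raise ValueError("total damages are zero; shares undefined")
    pop_total = float(population.loc[idx].sum())

    def group(order: pd.Index, frac: float) -> list:
        members, cum = [], 0.0
        for c in order:
            if cum < frac * pop_total:
                members.append(c)
            cum += float(population.loc[c])
        return members

    asc = gdp_pc.loc[idx].sort_values(kind="stable").index
    bottom = group(asc, bottom_frac)
    top = group(asc[::-1], top_frac)
    return {
        "bottom_share": float(loss_only.loc[bottom].sum() / total),
        "top_share": float(loss_only.loc[top].sum() / total),
        "bottom_countries": bottom,
        "top_countries": top,
        "total_losses": total,
        "total_gains": float(gains.sum()),
    }
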