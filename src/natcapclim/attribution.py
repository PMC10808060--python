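"""Apportioning national natural-capital totals to biomes.

For each country and benefit type the stage: (1) selects the valuation
records whose biome-cover profile is closest (Euclidean distance in percent
cover space) to the country's mean profile; (2) trains a 300-tree random
forest predicting log value per hectare from biome covers, GDP per capita
and the vegetated fraction; (3) perturbs each biome's cover by +10 percentage
points (holding all others constant, without renormalizing) to obtain
per-biome predicted values; (4) converts the predictions to scaling factors
relative to a reference biome; and (5) solves the perpetuity identity

    r * total = sum_b a_b * x_b * es_ref

for the reference per-hectare value, so the apportioned per-hectare values
reconstruct the national total exactly.  The same module estimates the
area / carbon / income elasticities of per-hectare value by a log-log OLS on
the valuation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor

from .config import (
    DISCOUNT_RATE,
    MIN_SUBSET_SIZE,
    N_TREES,
    PERTURBATION_PP,
    default_subset_size,
    log_decision,
    logger,
)


class InsufficientDataError(ValueError):
    """Too few valuation records to train a model."""


class NoVegetationError(ValueError):
    """A country has no vegetated area to apportion value over."""


def cover_columns(vegs: pd.DataFrame) -> list[str]:
    return [c for c in vegs.columns if c.startswith("cover_")]


# ---------------------------------------------------------------------------
# Subset selection
# ---------------------------------------------------------------------------


def select_subset(
    vegs: pd.DataFrame,
    profile: pd.Series,
    benefit_type: str,
    k: int | None = None,
) -> pd.DataFrame:
    """The k valuation records nearest the country's biome profile.

    Distances are Euclidean in percent-cover space over the biomes named by
    ``profile`` (index "cover_<biome>").  Ties are broken by record order, so
    selection is stable; records are filtered to ``benefit_type`` first.
    """
    cols = list(profile.index)
    sub = vegs[vegs["benefit_type"] == benefit_type]
    if k is None:
        k = default_subset_size(len(sub))
    if len(sub) < max(k if k else 0, MIN_SUBSET_SIZE):
        raise InsufficientDataError(
            f"only {len(sub)} {benefit_type} records, need >= "
            f"{max(k, MIN_SUBSET_SIZE)}"
        )
    d = np.sqrt(
        ((sub[cols].to_numpy(dtype=float)
          - profile.to_numpy(dtype=float)[None, :]) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(len(sub)), d))  # stable on ties
    return sub.iloc[order[:k]]


# ---------------------------------------------------------------------------
# Random-forest value model
# ---------------------------------------------------------------------------


@dataclass
class RfModel:
    """Deterministic (seeded) forest predicting log value per hectare."""

    forest: RandomForestRegressor
    feature_names: list[str]
    seed: int

    def predict_log_value(self, covers_pct: pd.Series, gdp_pc: float,
                          perc_covered: float) -> float:
        x = np.array(
            [[*covers_pct.loc[[f for f in self.feature_names
                               if f.startswith("cover_")]].to_numpy(),
              gdp_pc, perc_covered]]
        )
        return float(self.forest.predict(x)[0])


def train_value_model(subset: pd.DataFrame, seed: int = 0,
                      n_trees: int = N_TREES) -> RfModel:
    """Fit the forest on (biome covers, GDPpc, vegetated fraction) -> log v."""
    if subset.empty:
        raise InsufficientDataError("empty training subset")
    features = cover_columns(subset) + ["gdp_pc", "perc_covered"]
    y = np.log(subset["value_per_ha_yr"].to_numpy())
    if len(np.unique(y)) < 2:
        logger.warning("degenerate fit: fewer than 2 distinct target values")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    forest.fit(subset[features].to_numpy(), y)
    return RfModel(forest=forest, feature_names=features, seed=seed)


def perturbation_values(
    model: RfModel,
    profile: pd.Series,
    gdp_pc: float,
    perc_covered: float,
    bump_pp: float = PERTURBATION_PP,
) -> pd.Series:
    """Per-biome predicted values after a +bump_pp cover perturbation.

    Each biome's cover (percent) is raised by ``bump_pp`` with all other
    biomes held constant; perturbed vectors are passed to the model even if
    the total exceeds 100%.  Returns exp(prediction) per biome (> 0).
    """
    out = {}
    for col in profile.index:
        perturbed = profile.copy()
        perturbed[col] = perturbed[col] + bump_pp
        out[col.removeprefix("cover_")] = float(
            np.exp(model.predict_log_value(perturbed, gdp_pc, perc_covered))
        )
    return pd.Series(out, name="es_hat")


# ---------------------------------------------------------------------------
# Scaling and apportionment
# ---------------------------------------------------------------------------


def scaling_factors(es_hat: pd.Series, reference: str) -> pd.Series:
    """x_b = es_hat_b / es_hat_ref, so x at the reference biome is 1."""
    ref = es_hat.loc[reference]
    if ref <= 0:
        raise ValueError(f"non-positive reference prediction for {reference!r}")
    return (es_hat / ref).rename("x")


def apportion_natcap(
    total: float,
    areas: pd.Series,
    x: pd.Series,
    r: float = DISCOUNT_RATE,
) -> pd.Series:
    """Per-biome per-hectare annual values reconstructing the national stock.

    es_ref = r * total / sum_b a_b x_b and es_b = x_b * es_ref, so that
    sum_b a_b es_b / r = total holds exactly.
    """
    if total < 0:
        raise ValueError("natural-capital total must be >= 0")
    x = x.loc[areas.index]
    denom = float((areas * x).sum())
    if denom <= 0:
        raise NoVegetationError("all biome areas are zero")
    es_ref = r * total / denom
    return (x * es_ref).rename("value_per_ha_yr")


# ---------------------------------------------------------------------------
# Elasticities
# ---------------------------------------------------------------------------


@dataclass
class ElasticityEstimates:
    """Log-log elasticities of per-hectare value, one row per benefit type.

    ``table`` columns: benefit_type, term (area|carbon|income), coef, se,
    pvalue, provenance.  The pipeline default zeroes the market area and
    carbon elasticities downstream (no effect is detectable for market
    benefits), while reporting the raw estimates here.
    """

    table: pd.DataFrame

    def coef(self, benefit_type: str, term: str) -> float:
        row = self.table[(self.table.benefit_type == benefit_type)
                         & (self.table.term == term)]
        return float(row["coef"].iloc[0])

    def se(self, benefit_type: str, term: str) -> float:
        row = self.table[(self.table.benefit_type == benefit_type)
                         & (self.table.term == term)]
        return float(row["se"].iloc[0])


def estimate_elasticities(vegs: pd.DataFrame, min_records: int = 30) -> ElasticityEstimates:
    """OLS of log value on log site area, log carbon and log GDP per capita,
    fitted separately for non-market and market records."""
    rows = []
    for btype, sub in vegs.groupby("benefit_type"):
        if len(sub) < min_records:
            raise InsufficientDataError(
                f"{btype}: {len(sub)} records < {min_records}")
        X = np.column_stack(
            [
                np.log(sub["site_area_ha"]),
                np.log(sub["carbon_kg_m2"]),
                np.log(sub["gdp_pc"]),
            ]
        )
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), X])) < 4:
            raise np.linalg.LinAlgError("collinear or constant regressors")
        fit = sm.OLS(np.log(sub["value_per_ha_yr"].to_numpy()),
                     sm.add_constant(X)).fit()
        for i, term in enumerate(("area", "carbon", "income"), start=1):
            rows.append(
                {
                    "benefit_type": btype,
                    "term": term,
                    "coef": fit.params[i],
                    "se": fit.bse[i],
                    "pvalue": fit.pvalues[i],
                    "provenance": "estimated",
                }
            )
    return ElasticityEstimates(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Full attribution stage
# ---------------------------------------------------------------------------


@dataclass
class AttributionResult:
    """Per-hectare values, scaling factors and bookkeeping for one typology
    batch."""

    per_hectare: pd.DataFrame  # typology, country, biome, benefit_type, value_per_ha_yr
    scaling: pd.DataFrame      # typology, country, biome, benefit_type, x
    n_models: int


def attribute_all(
    vegs: pd.DataFrame,
    areas,  # CountryBiomeAreas
    accounts: pd.DataFrame,
    typologies: tuple[str, ...] = ("native",),
    r: float = DISCOUNT_RATE,
    k: int | None = None,
    seed: int = 0,
    benefit_types: tuple[str, ...] = ("non-market", "market"),
) -> AttributionResult:
    """Run the full attribution design: one model per (country, benefit type,
    typology).

    ``accounts`` must carry ``nonmarket_natcap`` and ``market_natcap`` per
    country; ``areas`` provides base-year hectares and cover profiles.  The
    reference biome of each country is its largest by area.  Countries whose
    eligible subset is too small inherit a pooled (all-record) model, logged.
    """
    amat = areas.area_matrix()
    per_country = areas.by_country
    stock_col = {"non-market": "nonmarket_natcap", "market": "market_natcap"}

    ph_rows, x_rows, n_models = [], [], 0
    for typology in typologies:
        for btype in benefit_types:
            pooled_model = None
            for ci, country in enumerate(amat.index):
                a_b = amat.loc[country]
                if a_b.sum() <= 0:
                    log_decision("attribution", country, "excluded_no_vegetation",
                                 typology=typology, benefit_type=btype)
                    continue
                territory = per_country.loc[country, "territory_ha"]
                profile = (a_b / territory * 100.0).rename(
                    index=lambda b: f"cover_{b}")
                model_seed = (seed * 1000003 + n_models) % (2**31 - 1)
                try:
                    subset = select_subset(vegs, profile, btype, k)
                    model = train_value_model(subset, seed=model_seed)
                except InsufficientDataError:
                    if pooled_model is None:
                        pooled = vegs[vegs["benefit_type"] == btype]
                        if len(pooled) < MIN_SUBSET_SIZE:
                            raise
                        pooled_model = train_value_model(pooled, seed=model_seed)
                    model = pooled_model
                    log_decision("attribution", country, "pooled_fallback",
                                 typology=typology, benefit_type=btype)
                n_models += 1
                gdp_pc = accounts.loc[country, "gdp_pc"]
                perc = per_country.loc[country, "perc_covered"]
                es_hat = perturbation_values(model, profile, gdp_pc, perc)
                reference = a_b.idxmax()
                x = scaling_factors(es_hat, reference)
                total = accounts.loc[country, stock_col[btype]]
                es = apportion_natcap(float(total), a_b, x, r)
                for b in a_b.index:
                    ph_rows.append(
                        {"typology": typology, "country": country, "biome": b,
                         "benefit_type": btype,
                         "value_per_ha_yr": float(es.loc[b])})
                    x_rows.append(
                        {"typology": typology, "country": country, "biome": b,
                         "benefit_type": btype, "x": float(x.loc[b]),
                         "reference_biome": reference})
    return AttributionResult(
        per_hectare=pd.DataFrame(ph_rows),
        scaling=pd.DataFrame(x_rows),
        n_models=n_models,
    )
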