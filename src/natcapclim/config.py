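"""Shared scientific defaults, units and logging for the natural-capital
climate-damage pipeline.

All monetary quantities are constant 2018 USD.  Areas are hectares, vegetation
carbon is kg m^-2, temperature anomalies are degrees Celsius relative to the
base period.  Every default below is either a published point value used by
the method (noted) or a package design choice (noted as "decision"); both can
be overridden through :class:`natcapclim.pipeline.RunConfig`.
"""

from __future__ import annotations

import logging

# ---------------------------------------------------------------------------
# Valuation / discounting
# ---------------------------------------------------------------------------

#: Consumption discount rate used in the perpetuity formula stock = flow / r
#: (World Bank wealth-accounting convention).
DISCOUNT_RATE: float = 0.03

#: Elasticity of per-hectare non-market ecosystem value w.r.t. biome area
#: (diminishing marginal utility of additional hectares).
ETA_AREA: float = -0.103

#: Elasticity of per-hectare non-market value w.r.t. vegetation carbon stock
#: (a 1% carbon increase raises the value by 0.282%).
ETA_CARBON: float = 0.282

#: Income elasticity of non-market ecosystem-service value (per % change in
#: GDP per capita), used in the ecosystem-service flow formula.
ETA_INCOME: float = 0.00596

# ---------------------------------------------------------------------------
# Attribution stage
# ---------------------------------------------------------------------------

#: Trees per random forest; RMSE improvement saturates around this size.
N_TREES: int = 300

#: Cover perturbation applied per biome when probing the forest, in
#: percentage points of cell cover.
PERTURBATION_PP: float = 10.0

#: Minimum number of valuation records needed to train a country model;
#: below this the pooled (global) model is used instead (decision).
MIN_SUBSET_SIZE: int = 10


def default_subset_size(n_eligible: int) -> int:
    """Nearest-neighbour subset size for the attribution stage.

    The selection rule keeps the k records closest to the country's biome
    profile; k = max(30, 25% of eligible records), capped at the table size
    (decision — the selection threshold is not pinned down by the method).
    """
    return min(n_eligible, max(30, int(round(0.25 * n_eligible))))


# ---------------------------------------------------------------------------
# Projection stage
# ---------------------------------------------------------------------------

#: Caps on |percentage change| of vegetated area / mean carbon admitted by
#: the per-hectare value adjustment (twice-the-data-range rule; the actual
#: range is not published, so 100% is the conservative default — decision).
CAP_AREA_PCT: float = 100.0
CAP_CARBON_PCT: float = 100.0

#: Reference ("present") period for baselines and temperature anomalies.
BASE_PERIOD: tuple[int, int] = (2016, 2020)

#: Decades of the damage panel: the 2030s through the 2090s.  Each decade
#: d covers calendar years [d, d+9]; trajectories are evaluated at the
#: decade-mean temperature anomaly (decision).
DECADES: tuple[int, ...] = tuple(range(2030, 2100, 10))

# ---------------------------------------------------------------------------
# Economy stage
# ---------------------------------------------------------------------------

#: Annual depreciation rate of manufactured capital (decision, RICE-family
#: convention).
DELTA_DEPRECIATION: float = 0.10

#: Years per simulation step (decision, RICE-family convention).
STEP_YEARS: int = 5

#: Default exogenous gross savings rate (decision).
SAVINGS_RATE: float = 0.25

#: Simulation horizon.
HORIZON: tuple[int, int] = (2015, 2100)

#: Macro regions used for the region-specific elasticity of the global
#: environmental good.
MACRO_REGIONS: tuple[str, ...] = ("ASIA", "LAM", "MAF", "OECD", "REF")

# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

EARTH_RADIUS_M: float = 6_371_000.0

# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

logger = logging.getLogger("natcapclim")


def log_decision(stage: str, country: object, action: str, **details: object) -> None:
    """One structured line per country-level decision (exclusion, fallback,
    clamp), so pipeline runs are auditable."""
    extra = " ".join(f"{k}={v}" for k, v in details.items())
    logger.info("%s country=%s action=%s %s", stage, country, action, extra)
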