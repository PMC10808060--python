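# Methods

This note documents the models implemented in `natcapclim`, the defaults
and their rationale, what the synthetic world does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Natural capital as a perpetuity

Both stocks are valued by the perpetuity formula `stock = flow / r` with a
consumption discount rate `r = 0.03` (the wealth-accounting convention).
Per-hectare annual values are estimated once for the base year (2018) and
held fixed over the horizon; stocks change through biome areas and, for the
non-market stock, through the value-adjustment multiplier below. This
"time-invariant benefits" assumption mirrors how national accounts
themselves are built and makes the projection a pure function of the
vegetation response.

## Attribution of national stocks to biomes

For country c and benefit type i the stage trains a random forest
`RF_{i,c}` on the k valuation records nearest the country's biome-cover
profile and probes it by raising each biome's cover 10 percentage points,
holding all others constant. Key choices:

- **Subset rule.** The selection threshold is not pinned down by the
  method, so the default keeps `k = max(30, 25% of eligible records)`:
  enough locality to matter, enough data to train a forest. Distance ties
  break on record order, so selection is stable. Countries with too few
  records inherit a pooled (all-record) model, logged per country.
- **No renormalization of perturbed profiles.** The +10 pp probe may push
  total cover past 100%; the vector is passed to the forest unmodified,
  because the probe is a ceteris-paribus question, not a composition.
- **Reference biome** = the country's largest biome by base-year area (the
  best-supported prediction). Scaling factors are `x_b = ês_b / ês_ref`
  with `x_ref = 1`; the apportionment `es_ref = r·total / Σ_b a_b x_b`
  then reconstructs the national stock exactly — this identity is asserted
  at 1e-10 relative tolerance in the tests and is independent of forest
  quality (the forest only shapes the split between biomes).
- **Forest hyperparameters.** 300 trees (error saturates around there),
  everything else at library defaults, seed mandatory; same seed + same
  subset gives identical predictions.
- **Elasticity regression.** Log value/ha on log site area, log carbon and
  log GDP per capita, plain OLS, separately by benefit type. No fixed
  effects or cover controls — and the synthetic generator matches this
  specification exactly (covariates drawn independently of the cover
  profile), so recovery of the planted elasticities is unbiased. Market
  area/carbon elasticities are estimated but zeroed downstream: no market
  effect is detectable, and the market stock responds to area only.

## Projection and the value adjustment

The non-market multiplier is `1 + (0.282·ċ − 0.103·ȧ)/100`, with ȧ and ċ
the percentage changes of total vegetated area and of cover-weighted mean
vegetation carbon against the 2016–2020 baseline. Because the underlying
elasticities are local estimates, both changes are clamped to caps before
the multiplier is evaluated (defaults ±100%, configurable — the
twice-the-data-range rule cannot be reproduced without the original
valuation data), and the multiplier is floored at 0 so values cannot turn
negative. The multiplier applies uniformly across a country's biomes; a
per-biome variant would need per-biome elasticities the data cannot
support. Trajectories are evaluated at decade midpoints (2035 … 2095)
using the decade-mean anomaly, matching the decadal resolution of the
damage panel; with the linear vegetation response this equals the decade
mean of annual evaluations.

## Damage functions

Per country and stock, the decadal relative changes are fitted by
least squares through the origin on the anomaly with climate-model and
pathway fixed effects (one omitted reference level each — the explicit
zero intercept is what identifies θ). Plain OLS standard errors are the
default; run-clustered errors are a config switch. The anomaly is the
global mean relative to 2016–2020. With a single run the fit reduces to
the closed-form through-origin slope, which the tests exploit as an
oracle. The scenario-run matrix (which climate models × pathways) is
configuration; the default synthetic matrix is 4 × 3.

## The economy

`GDP = TFP · S^b_r · L^γ1 · K^γ2 · mN^γ3` with `S` the global sum of
non-market natural capital (an environmental public good; b varies by
macro region) and constant returns over the three private factors.

- **Estimation.** γ1 and the region-specific b come from a GDP-weighted
  panel regression on logs with country fixed effects and year effects,
  standard errors clustered by macro region. Because S is a single global
  series, a full set of year dummies is exactly collinear with the
  region-interacted log S block (the interactions sum to log S_t, a pure
  function of the year); the year effects therefore omit two reference
  years — one for the usual level redundancy, one to break that
  collinearity — and the design rank is checked. The estimated year
  effects are consequently identified only up to that restriction, which
  is immaterial for the structural coefficients when true year effects are
  absent (as in the synthetic panel).
- **Calibration.** γ3 is each country's timber-rent share of GDP,
  γ2 = 1 − γ1 − γ3. TFP is solved step by step so a baseline with natural
  capital frozen at base-year levels reproduces the exogenous GDP path to
  machine precision; TFP is then held fixed in the damaged run, so damages
  propagate only through S, mN and the capital stock.
- **Dynamics.** 5-year steps over 2015–2100, capital accumulation
  `K' = K(1−δ)^Δ + Δ·s·GDP` with δ = 0.10 yr⁻¹ and an exogenous savings
  rate (default 0.25); savings are not re-optimized in the damaged run.
  Damaged stocks follow `nN_t = max(0, nN_0(1 + θ_n ΔT_t))`.
- **Reporting.** The ecosystem-service flow is
  `ES = nN · r · (1 + 0.00596 · %ΔGDPpc)` with the income change measured
  against the run's own first year. Global impacts are population-weighted
  at the evaluation year (2100 population). Damage shares rank countries
  by baseline GDP per capita and assign whole countries to the bottom-50%
  / top-10% population groups while the cumulative population before a
  country is below the threshold (groups are never empty; gains are
  excluded from both numerator and denominator and reported separately).

## The synthetic world

The generator is a pure function of (config, truth, seed); per-generator
streams derive deterministically from the master seed.

- **Grid and countries.** Default 36 × 72 (5° cells), 8 countries tiling
  the vegetated rows as contiguous snake-order runs, 4 biomes as Gaussian
  latitude bands under a trimodal vegetated-fraction target (equatorial
  peak plus two boreal bands). Cell areas use spherical geometry.
- **Vegetation response.** Linear in the anomaly:
  `cover_t = clip(cover_0 (1 + s·ΔT) + ε, 0, 1)`, carbon analogous. The
  default sensitivity is an income gradient from −0.05 /°C (poorest) to
  +0.005 /°C (richest), emulating tropical losses and modest high-latitude
  gains; it is exactly linear when noiseless, which is what makes the
  closed-form damage-slope oracles possible.
- **Valuation records.** `log v = b0 + Σ_b w_b cover_b/100 + η_a log area
  + η_c log carbon + η_y log GDPpc + ε` with the published elasticities
  planted (−0.103, 0.282, 0.00596; market records null). Site covariates
  are drawn independently of the cover profile so the three-regressor
  elasticity regression is unbiased; the biome weights are scaled so the
  (omitted) cover term stays a modest signal next to the stated log-noise,
  keeping the stated noise level the binding study condition.
- **Accounts.** GDP per capita spans 1,000–40,000 log-uniformly across
  countries; natural-capital intensity (nN/GDP from ~0.6 down to ~0.08),
  timber shares (0.022 → 0.002), population density and the
  environmental-good elasticity b (regions ranked MAF > ASIA > LAM > REF >
  OECD, joined by income quantile) all decline with income — the stylized
  facts that make the damage distribution regressive. Base-year GDP
  satisfies the production function exactly under the planted parameters
  (TFP is solved for and stored). The 20-year historical estimation panel
  plants the regression's own specification (a common market-natcap
  elasticity equal to the mean timber share; country effects absorb the
  base-year level difference against the country-specific simulation
  parameters), so noiseless recovery is exact.

What passing tests therefore show: the pipeline's identities, estimators
and orderings are correct for worlds obeying these assumptions. What they
do not show: performance under real vegetation-model output (non-linear,
spatially correlated responses; biome replacement vs. area change),
real valuation data (selection, heterogeneity, spatial clustering far from
the planted log-linear model) or real accounts (measurement error,
non-Cobb-Douglas production). Headline magnitudes from the default world
are illustrative of mechanism, not predictions.

## Numerical choices and degenerate inputs

- Exact identities (apportionment reconstruction, TFP neutrality) are
  enforced to 1e-10 relative; closed-form oracles to 1e-8 or tighter.
- Zero-vegetation countries, zero base-year stocks and zero baseline GDP
  are excluded with one structured log line each, never silently imputed.
- A zero production input with a positive exponent yields zero output with
  a warning; negative inputs raise. Rank-deficient regression designs
  raise rather than fall back to pseudo-inverse estimates.
- Problem sizes (grid, record counts, run matrix, 5-year steps) are chosen
  so a full pipeline run completes in well under a minute; all scale up
  through configuration without code changes.

## Known limitations

Whole-cell country attribution (no areal splitting at borders); a single
global anomaly rather than spatial climate fields; exogenous savings; no
emissions optimization or policy feedback; the value-adjustment caps are a
configurable stand-in for a data-range rule that needs the original
valuation sample; and the synthetic biome typologies are label-level
stand-ins (one grid serves all three), so cross-typology spread in the
outputs reflects forest seeds, not model structure.
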