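"""Per-country climate damage functions for natural capital.

The damage model is linear through the origin: the relative change of a
country's natural capital equals theta times the global mean temperature
anomaly.  Decadal point estimates from the scenario runs (climate model x
forcing pathway) are pooled and fitted with

    d_nN_hat = 0 + theta * dT + alpha_gcm + alpha_rcp + eps

i.e. least squares with NO global intercept; the climate-model and pathway
fixed effects use one omitted reference level each so theta stays identified.
Plain OLS standard errors are the default, with an optional run-clustered
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import DECADES


class SingularFitError(ValueError):
    """The damage-regression design matrix is rank deficient."""


def assemble_panel(
    changes: pd.DataFrame,
    runs: pd.DataFrame,
    decades: tuple[int, ...] = DECADES,
) -> pd.DataFrame:
    """Decadal damage panel across scenario runs.

    ``changes`` is tidy (run_id, year, country, d_nN_hat, d_mN_hat);
    ``runs`` is the scenario table with run_id, gcm, rcp and a ``path``
    TemperaturePath per run.  For each (country, run, decade) the decade-mean
    anomaly is paired with the decade-mean relative changes; the output has
    runs x decades rows per country.
    """
    missing = set(changes["run_id"]) - set(runs["run_id"])
    if missing:
        raise ValueError(f"runs without a temperature path: {sorted(missing)}")
    run_info = runs.set_index("run_id")

    rows = []
    for (run_id, country), grp in changes.groupby(["run_id", "country"]):
        path = run_info.loc[run_id, "path"]
        for decade in decades:
            sel = grp[(grp.year >= decade) & (grp.year < decade + 10)]
            if sel.empty:
                raise ValueError(
                    f"run {run_id}: no change estimates within decade {decade}s")
            rows.append(
                {
                    "country": country,
                    "run_id": run_id,
                    "gcm": run_info.loc[run_id, "gcm"],
                    "rcp": run_info.loc[run_id, "rcp"],
                    "decade": decade,
                    "dT": path.decade_mean(decade),
                    "d_nN_hat": float(sel["d_nN_hat"].mean()),
                    "d_mN_hat": float(sel["d_mN_hat"].mean()),
                }
            )
    panel = pd.DataFrame(rows)
    return panel.sort_values(["country", "run_id", "decade"]).reset_index(drop=True)


@dataclass
class DamageCoefficient:
    """theta (fractional natural-capital change per deg C) with its OLS
    standard error and p-value."""

    country: str
    target: str  # "nN" | "mN"
    theta: float
    se: float
    pvalue: float
    typology: str = "native"


def _design(panel: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [panel["dT"].to_numpy()[:, None]]
    names = ["dT"]
    for var in ("gcm", "rcp"):
        levels = sorted(panel[var].unique())
        for lev in levels[1:]:  # first level is the omitted reference
            cols.append((panel[var] == lev).to_numpy(float)[:, None])
            names.append(f"{var}[{lev}]")
    return np.hstack(cols), names


def fit_damage_function(
    panel: pd.DataFrame,
    country: str,
    target: str = "nN",
    cluster_by_run: bool = False,
    typology: str = "native",
) -> DamageCoefficient:
    """Through-origin least squares of the decadal changes on the anomaly.

    Requires at least two rows with distinct anomalies.  With a single run
    the fixed-effect dummies vanish and the fit reduces to the closed-form
    through-origin slope sum(dT * y) / sum(dT^2).
    """
    sub = panel[panel.country == country]
    if sub["dT"].nunique() < 2 and len(sub) < 2:
        raise ValueError(f"{country}: need >= 2 rows with distinct anomalies")
    y = sub["d_nN_hat" if target == "nN" else "d_mN_hat"].to_numpy()
    X, names = _design(sub)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(f"{country}: rank-deficient damage design")
    if cluster_by_run:
        fit = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": sub["run_id"].to_numpy()})
    else:
        fit = sm.OLS(y, X).fit()
    i = names.index("dT")
    return DamageCoefficient(
        country=country,
        target=target,
        theta=float(fit.params[i]),
        se=float(fit.bse[i]),
        pvalue=float(fit.pvalues[i]),
        typology=typology,
    )


def fit_all(panel: pd.DataFrame, cluster_by_run: bool = False,
            typology: str = "native") -> pd.DataFrame:
    """Damage-coefficient table (country, target, theta, se, p, typology)."""
    rows = []
    for country in sorted(panel["country"].unique()):
        for target in ("nN", "mN"):
            coef = fit_damage_function(panel, country, target,
                                       cluster_by_run, typology)
            rows.append(
                {
                    "country": coef.country,
                    "target": coef.target,
                    "theta": coef.theta,
                    "se": coef.se,
                    "pvalue": coef.pvalue,
                    "typology": coef.typology,
                }
            )
    return pd.DataFrame(rows)
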