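"""Weighted regression of state-level effects on emissions and geography.

Explains the estimated per-state intervention effects ``Delta_j`` with
2014 emissions-source shares (fire, stationary, mobile — biogenic is the
omitted remainder), population density, and Census region, including all
two-factor interactions among those five predictors. Effects estimated
from different states carry different bootstrap uncertainty, so the fit
is weighted least squares; the recommended weights are the inverse
bootstrap variances of the ``Delta_j`` estimates.

Conventions: population density is log-transformed (strongly right-skewed
across states); continuous predictors are centered before interactions
are formed so main effects keep their interpretation at average predictor
values; region enters as dummies with Northeast as the reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["DesignInfo", "RegressionResult", "build_design", "fit_wmlr"]

REGIONS = ("Northeast", "Midwest", "South", "West")
CONTINUOUS = ("prop_fire", "prop_stationary", "prop_mobile", "log_density")


@dataclass
class DesignInfo:
    """A design matrix plus a record of what was dropped and why."""

    X: pd.DataFrame  # includes "const"
    dropped: list[str]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


@dataclass
class RegressionResult:
    """WLS fit summary: estimates, SEs, t, p, R2, adjusted R2, residuals."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    resid: np.ndarray
    weights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        ).rename_axis("term")


def _validate_covariates(cov: pd.DataFrame) -> None:
    required = {"prop_fire", "prop_stationary", "prop_mobile", "population_density", "region"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate table missing columns {sorted(missing)}")
    props = cov[["prop_fire", "prop_stationary", "prop_mobile"]].to_numpy(dtype=float)
    if (props < 0).any() or (props > 1).any():
        raise ValueError("source proportions must lie in [0, 1]")
    if (props.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("fire + stationary + mobile proportions must be <= 1")
    if (cov["population_density"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("population density must be positive")


def build_design(
    covariates: pd.DataFrame,
    *,
    center: bool = True,
    log_density: bool = True,
    region_reference: str = "Northeast",
) -> DesignInfo:
    """Main effects + all two-factor interactions among the five predictors.

    Predictors: three source proportions, (log) population density, and
    region dummies. Interactions are products of continuous pairs and of
    each continuous predictor with each region dummy; region x region
    terms do not exist (one factor). Columns that do not increase the
    design rank are dropped and reported; a degenerate single-level
    region drops the factor entirely with a warning.
    """
    _validate_covariates(covariates)
    n = len(covariates)
    dropped: list[str] = []

    cont = pd.DataFrame(index=covariates.index)
    for c in ("prop_fire", "prop_stationary", "prop_mobile"):
        cont[c] = covariates[c].astype(float)
    dens = covariates["population_density"].astype(float)
    cont["log_density"] = np.log(dens) if log_density else dens
    if center:
        cont = cont - cont.mean()

    region = covariates["region"].astype(str)
    levels = [r for r in pd.unique(region)]
    if len(levels) < 2:
        warnings.warn(
            f"region has a single level ({levels[0]}); factor dropped from the design",
            UserWarning,
            stacklevel=2,
        )
        dummies = pd.DataFrame(index=covariates.index)
        dropped.append("region (single level)")
    else:
        counts = region.value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValueError(
                f"regions with fewer than 2 states: {dict(thin)}; merge or drop them"
            )
        order = [r for r in REGIONS if r in levels] + [r for r in levels if r not in REGIONS]
        ref = region_reference if region_reference in levels else order[0]
        dummies = pd.DataFrame(
            {f"region[{lv}]": (region == lv).astype(float) for lv in order if lv != ref}
        )

    X = pd.DataFrame({"const": np.ones(n)}, index=covariates.index)
    for c in cont.columns:
        X[c] = cont[c]
    for c in dummies.columns:
        X[c] = dummies[c]
    # continuous x continuous interactions
    for a, b in combinations(cont.columns, 2):
        X[f"{a}:{b}"] = cont[a] * cont[b]
    # continuous x region interactions
    for a in cont.columns:
        for dcol in dummies.columns:
            X[f"{a}:{dcol}"] = cont[a] * dummies[dcol]

    # drop rank-deficient columns greedily (constant and mains first, by order)
    keep: list[str] = []
    mat = np.empty((n, 0))
    for col in X.columns:
        cand = np.column_stack([mat, X[col].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > mat.shape[1]:
            keep.append(col)
            mat = cand
        else:
            dropped.append(col)
    if dropped:
        logger.warning("design columns dropped: %s", dropped)
    X = X[keep]
    if n <= X.shape[1]:
        raise ValueError(
            f"{X.shape[1]} parameters for {n} states: prune interactions or add states"
        )
    return DesignInfo(X=X, dropped=dropped)


def fit_wmlr(
    design: DesignInfo | pd.DataFrame,
    outcomes: np.ndarray | pd.Series,
    weights: np.ndarray | None = None,
) -> RegressionResult:
    """Weighted least squares of per-state effects on the design.

    ``weights`` are per-state precisions (larger = more trusted), e.g.
    inverse bootstrap variances of the effect estimates; None gives OLS.
    Estimates are invariant to rescaling all weights by a constant.
    """
    X = design.X if isinstance(design, DesignInfo) else design
    y = np.asarray(outcomes, dtype=float)
    if len(y) != len(X):
        raise ValueError("outcomes and design have different lengths")
    if weights is None:
        weights = np.ones(len(y))
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any() or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite and strictly positive")
    if len(y) <= X.shape[1]:
        raise ValueError("need more states than parameters")
    res = sm.WLS(y, X, weights=weights).fit()
    if not np.all(np.isfinite(res.params)):
        raise np.linalg.LinAlgError("singular weighted normal equations")
    return RegressionResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        resid=np.asarray(res.resid),
        weights=weights,
    )
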