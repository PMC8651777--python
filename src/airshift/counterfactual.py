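"""SARIMA counterfactual forecasting with meteorological covariates.

The counterfactual question is: what would weekly pollutant levels have
been over the forecast window had the intervention not occurred? A
seasonal ARIMA model with exogenous weather regressors (temperature,
precipitation, humidity) is fit to the multi-year training window of each
bootstrap replicate and projected over the forecast horizon using the
weather actually observed there — the counterfactual removes the
intervention, not the weather. Averaging the replicate forecasts gives
the bagged prediction ``c_pred`` with empirical percentile bands.

The forecasting code path takes no intervention date: deviations are
attributed to the intervention only downstream, by comparing observed and
counterfactual levels before versus after it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import kpss

from .ensemble import generate_ensemble, stl_decompose
from .types import CounterfactualForecast, WeeklySeries

logger = logging.getLogger(__name__)

__all__ = [
    "SarimaSpec",
    "OrderCaps",
    "ReplicateFailure",
    "select_order",
    "fit_and_forecast",
    "bag_forecasts",
    "run_state",
    "validation_run",
]


class ReplicateFailure(RuntimeError):
    """A single bootstrap replicate failed to fit or forecast."""


@dataclass(frozen=True)
class OrderCaps:
    """Search caps for stepwise order selection.

    At weekly seasonality (m=52) only 5 seasonal cycles fit in a 5-year
    training window, so seasonal orders are capped at 1 and at most one
    seasonal difference is allowed.
    """

    max_p: int = 2
    max_q: int = 2
    max_P: int = 1
    max_Q: int = 1
    max_d: int = 2
    max_D: int = 1


@dataclass
class SarimaSpec:
    """A selected SARIMA specification and its fit summary.

    ``fitted_params`` carries the full-ML parameter vector from the
    series the spec was selected on; refits of the same spec (bootstrap
    replicates) warm-start from it.
    """

    order: tuple[int, int, int]
    seasonal_order: tuple[int, int, int, int]
    aicc: float
    trend: str | None = None
    exog_coefs: dict[str, float] = field(default_factory=dict)
    sigma2: float = float("nan")
    fitted_params: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        p, d, q = self.order
        P, D, Q, m = self.seasonal_order
        if min(p, d, q, P, D, Q) < 0:
            raise ValueError("all SARIMA orders must be non-negative")
        if d + D > 3:
            raise ValueError("d + D must be <= 3")
        if m < 1 and (P or D or Q):
            raise ValueError("seasonal terms require a seasonal period m >= 1")

    @property
    def n_arma_params(self) -> int:
        p, _, q = self.order
        P, _, Q, _ = self.seasonal_order
        return p + q + P + Q


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_sarimax(
    y, exog, order, seasonal_order, trend, maxiter=100, start_params=None,
    concentrate_scale=False,
):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            y,
            exog=exog,
            order=order,
            seasonal_order=seasonal_order,
            trend=trend,
            enforce_stationarity=True,
            enforce_invertibility=True,
            concentrate_scale=concentrate_scale,
        )
        # a constant series has a degenerate likelihood (sigma2 -> 0) on
        # which L-BFGS stalls short of the optimum; Powell handles it
        method = "powell" if np.ptp(np.asarray(y, dtype=float)) == 0 else "lbfgs"
        return model.fit(
            disp=0, method=method, maxiter=maxiter, start_params=start_params
        )


def _try_aicc(y, exog, order, seasonal_order, trend) -> float:
    # scale concentrated out of the likelihood during the search: same
    # maximum, one fewer free parameter per optimisation, noticeably faster
    try:
        res = _fit_sarimax(
            y, exog, order, seasonal_order, trend, maxiter=35, concentrate_scale=True
        )
    except (Exception,):
        return np.inf
    k = len(res.params) + 1  # count the concentrated variance as estimated
    aicc = _aicc(res.llf, k, res.nobs)
    return aicc if np.isfinite(aicc) else np.inf


def _choose_d(y: np.ndarray, max_d: int, alpha: float = 0.05) -> int:
    """Number of ordinary differences: difference until KPSS accepts stationarity."""
    d = 0
    z = np.asarray(y, dtype=float)
    while d < max_d:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, pval, *_ = kpss(z, regression="c", nlags="auto")
            except (ValueError, OverflowError):
                break
        if pval >= alpha:  # stationarity not rejected
            break
        z = np.diff(z)
        d += 1
    return d


def _choose_D(y: np.ndarray, m: int, max_D: int, threshold: float = 0.64) -> int:
    """Seasonal differences via the STL seasonal-strength heuristic.

    Strength ``F_s = max(0, 1 - var(remainder)/var(seasonal + remainder))``;
    one seasonal difference is taken when ``F_s`` exceeds the threshold.
    """
    if max_D < 1 or m < 2 or len(y) < 2 * m:
        return 0
    dec = stl_decompose(np.asarray(y, dtype=float), m)
    denom = np.var(dec.seasonal + dec.remainder)
    if denom == 0:
        return 0
    strength = max(0.0, 1.0 - np.var(dec.remainder) / denom)
    return 1 if strength >= threshold else 0


def select_order(
    y: np.ndarray,
    exog: np.ndarray | pd.DataFrame | None,
    m: int,
    caps: OrderCaps = OrderCaps(),
) -> SarimaSpec:
    """Stepwise search over SARIMA orders minimising bias-corrected AIC.

    Hyndman–Khandakar-style: ``d`` by repeated KPSS tests, ``D`` by STL
    seasonal strength, then a deterministic stepwise walk over
    ``(p, q, P, Q)`` from a small set of starting models, accepting the
    neighbour with the lowest AICc until no neighbour improves. Ties
    break toward fewer ARMA parameters. A constant is included whenever
    no differencing is applied.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    seasonal = m >= 2 and n >= 2 * m
    D = _choose_D(y, m, caps.max_D) if seasonal else 0
    y_for_d = y[m:] - y[:-m] if D else y
    d = _choose_d(y_for_d, caps.max_d)
    trend = "c" if d + D == 0 else None

    if seasonal:
        starts = [(2, 2, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)]
    else:
        starts = [(2, 2, 0, 0), (0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0)]

    def clip(c):
        p, q, P, Q = c
        if not (0 <= p <= caps.max_p and 0 <= q <= caps.max_q):
            return None
        if not (0 <= P <= caps.max_P and 0 <= Q <= caps.max_Q):
            return None
        if not seasonal and (P or Q):
            return None
        return c

    cache: dict[tuple, float] = {}

    def score(c) -> float:
        if c not in cache:
            p, q, P, Q = c
            cache[c] = _try_aicc(y, exog, (p, d, q), (P, D, Q, m) if seasonal else (0, 0, 0, 0), trend)
        return cache[c]

    def better(a, b) -> bool:
        """a strictly better than b: lower AICc, ties toward fewer parameters."""
        sa, sb = score(a), score(b)
        if sa == sb:
            return sum(a) < sum(b)
        return sa < sb

    candidates = [c for c in (clip(s) for s in starts) if c is not None]
    if not candidates:
        raise ValueError("order caps exclude every starting model")
    best = candidates[0]
    for c in candidates[1:]:
        if better(c, best):
            best = c

    moves = [(1, 0, 0, 0), (-1, 0, 0, 0), (0, 1, 0, 0), (0, -1, 0, 0),
             (0, 0, 1, 0), (0, 0, -1, 0), (0, 0, 0, 1), (0, 0, 0, -1),
             (1, 1, 0, 0), (-1, -1, 0, 0), (0, 0, 1, 1), (0, 0, -1, -1)]
    improved = True
    while improved:
        improved = False
        for mv in moves:
            c = clip(tuple(np.add(best, mv)))
            if c is None:
                continue
            if better(c, best):
                best = c
                improved = True
                break

    if not np.isfinite(score(best)):
        attempted = sorted(cache)
        raise RuntimeError(f"no SARIMA model converged; attempted orders {attempted}")

    p, q, P, Q = (int(v) for v in best)
    seasonal_order = (P, D, Q, m) if seasonal else (0, 0, 0, 0)
    res = _fit_sarimax(y, exog, (p, d, q), seasonal_order, trend)
    exog_names = []
    if exog is not None:
        exog_names = (
            list(exog.columns)
            if isinstance(exog, pd.DataFrame)
            # statsmodels' default names for unnamed exog columns are 1-based
            else [f"x{i + 1}" for i in range(np.atleast_2d(np.asarray(exog)).shape[1])]
        )
    param_names = list(res.param_names)
    coefs = {
        name: float(res.params[param_names.index(name)])
        for name in exog_names
        if name in param_names
    }
    sigma2 = (
        float(res.params[param_names.index("sigma2")])
        if "sigma2" in param_names
        else float("nan")
    )
    return SarimaSpec(
        order=(p, d, q),
        seasonal_order=seasonal_order,
        aicc=float(score(best)),
        trend=trend,
        exog_coefs=coefs,
        sigma2=sigma2,
        fitted_params=np.asarray(res.params),
    )


def fit_and_forecast(
    y: np.ndarray,
    exog: np.ndarray | pd.DataFrame | None,
    exog_future: np.ndarray | pd.DataFrame | None,
    spec: SarimaSpec,
    horizon: int = 16,
    start_params: np.ndarray | None = None,
    maxiter: int = 100,
    concentrate_scale: bool = False,
) -> tuple[np.ndarray, "object"]:
    """Fit one series under a fixed spec and return its mean forecast path.

    Returns ``(forecast, fitted_results)``; the statsmodels results object
    is exposed so callers can warm-start replicate refits and compute
    in-sample assessment statistics.
    """
    if exog_future is not None:
        nf = np.atleast_2d(np.asarray(exog_future)).shape[0]
        if nf < horizon:
            raise ValueError(f"need {horizon} future covariate rows, got {nf}")
    try:
        res = _fit_sarimax(
            y, exog, spec.order, spec.seasonal_order, spec.trend,
            maxiter=maxiter, start_params=start_params,
            concentrate_scale=concentrate_scale,
        )
        fc = np.asarray(res.get_forecast(horizon, exog=exog_future).predicted_mean)
    except Exception as exc:  # non-convergence, LinAlgError, ...
        raise ReplicateFailure(str(exc)) from exc
    if not np.all(np.isfinite(fc)):
        raise ReplicateFailure("non-finite forecast values")
    return fc, res


def bag_forecasts(
    paths: np.ndarray,
    c_obs: np.ndarray,
    *,
    state: str = "",
    pollutant: str = "",
    week_start: pd.DatetimeIndex | None = None,
    n_requested: int | None = None,
    min_survival: float = 0.5,
) -> CounterfactualForecast:
    """Average surviving replicate forecasts into the bagged counterfactual.

    Aborts when fewer than ``max(2, min_survival * n_requested)`` paths
    survive — a high non-convergence rate invalidates the bag.
    """
    paths = np.atleast_2d(np.asarray(paths, dtype=float))
    n_surviving, horizon = paths.shape
    if n_requested is None:
        n_requested = n_surviving
    needed = max(2, int(np.ceil(min_survival * n_requested)))
    if n_surviving < needed:
        raise RuntimeError(
            f"only {n_surviving}/{n_requested} replicates converged "
            f"({n_surviving / n_requested:.0%}); need at least {needed}"
        )
    if week_start is None:
        week_start = pd.date_range("2020-01-01", periods=horizon, freq="7D")
    return CounterfactualForecast(
        state=state,
        pollutant=pollutant,
        week_start=week_start,
        replicate_paths=paths,
        c_pred=paths.mean(axis=0),
        lo95=np.percentile(paths, 2.5, axis=0),
        hi95=np.percentile(paths, 97.5, axis=0),
        c_obs=np.asarray(c_obs, dtype=float),
        n_requested=int(n_requested),
    )


def run_state(
    series: WeeklySeries,
    *,
    B: int = 1000,
    m: int = 52,
    block_length: int = 24,
    caps: OrderCaps = OrderCaps(),
    order_policy: str = "fixed",
    path_mode: str = "simulate",
    seed: int | np.random.Generator | None = None,
    include_original: bool = True,
) -> CounterfactualForecast:
    """Full bagged-SARIMA counterfactual for one state x pollutant series.

    Pipeline: bootstrap the training window (`B` replicates), select
    orders, fit each replicate, forecast the horizon with the observed
    forecast-period weather, and bag. With ``order_policy="fixed"``
    (default) orders are selected once on the original training series and
    replicate fits only re-estimate coefficients, warm-started from the
    original fit; ``"per_replicate"`` re-runs the stepwise search on every
    replicate.

    ``path_mode`` controls what each replicate contributes to the bag:
    ``"simulate"`` (default) draws one future trajectory from the fitted
    model, so the replicate spread carries both parameter and innovation
    uncertainty and the percentile bands are predictive; ``"mean"`` uses
    each replicate's mean forecast path, whose spread reflects fit
    uncertainty only (narrower bands, same bagged mean in expectation).

    The intervention date is not an input: the forecast is agnostic to it.
    """
    if order_policy not in ("fixed", "per_replicate"):
        raise ValueError("order_policy must be 'fixed' or 'per_replicate'")
    if path_mode not in ("simulate", "mean"):
        raise ValueError("path_mode must be 'simulate' or 'mean'")
    horizon = series.horizon
    y = series.train_values
    X = series.train_covariates.to_numpy(dtype=float)
    Xf = series.forecast_covariates.to_numpy(dtype=float)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ens = generate_ensemble(
        y, B, period=m, block_length=block_length, seed=rng,
        include_original=include_original,
    )
    spec = select_order(y, X, m, caps=caps)
    # warm start for concentrated replicate fits: the full-ML vector from
    # order selection minus the trailing sigma2 (concentrated out)
    start = spec.fitted_params[:-1] if spec.fitted_params is not None else None

    paths, n_failed = [], 0
    for b in range(ens.B):
        yb = ens.replicates[b]
        try:
            if order_policy == "per_replicate":
                spec_b = select_order(yb, X, m, caps=caps)
                fc, res = fit_and_forecast(yb, X, Xf, spec_b, horizon=horizon)
            else:
                fc, res = fit_and_forecast(
                    yb, X, Xf, spec, horizon=horizon, start_params=start,
                    maxiter=25, concentrate_scale=True,
                )
            if path_mode == "simulate":
                fc = np.asarray(
                    res.simulate(
                        horizon, anchor="end", exog=Xf,
                        random_state=int(rng.integers(2**31)),
                    )
                )
                if not np.all(np.isfinite(fc)):
                    raise ReplicateFailure("non-finite simulated path")
            paths.append(fc)
        except ReplicateFailure as exc:
            n_failed += 1
            logger.info("state %s replicate %d dropped: %s", series.state, b, exc)
    if n_failed:
        logger.warning(
            "state %s: %d/%d replicates failed to converge", series.state, n_failed, ens.B
        )
    return bag_forecasts(
        np.array(paths),
        series.forecast_values,
        state=series.state,
        pollutant=series.pollutant,
        week_start=series.forecast_week_start,
        n_requested=ens.B,
    )


def validation_run(
    series: WeeklySeries,
    *,
    split_index: int | None = None,
    horizon: int | None = None,
    m: int = 52,
    **kwargs,
) -> CounterfactualForecast:
    """Re-run the counterfactual machinery on a pre-intervention year.

    The split is shifted back so both the training window and the
    evaluation horizon predate the real forecast period; the default
    shift is ``max(horizon, m)`` weeks, which at weekly seasonality
    reproduces a train-through-previous-December / predict-January-to-
    April layout. Output feeds the same deviation and APE computations,
    giving a no-intervention benchmark of forecast accuracy.
    """
    if horizon is None:
        horizon = series.horizon
    if split_index is None:
        split_index = series.split_index - max(horizon, m)
    if split_index + horizon > series.split_index:
        raise ValueError(
            "validation horizon would overlap the true forecast period "
            f"(split {split_index} + horizon {horizon} > {series.split_index})"
        )
    if split_index < 2 * m:
        raise ValueError("too little training data before the validation split")
    end = split_index + horizon
    sub = WeeklySeries(
        state=series.state,
        pollutant=series.pollutant,
        week_start=series.week_start[:end],
        values=series.values[:end],
        covariates=series.covariates.iloc[:end].reset_index(drop=True),
        split_index=split_index,
    )
    return run_state(sub, m=m, **kwargs)
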