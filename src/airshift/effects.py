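"""Intervention-effect statistics on counterfactual deviations.

Weekly deviations ``delta_i = C_obs_i - C_pred_i`` compare observed
pollution with the bagged counterfactual over the forecast horizon. The
per-state effect contrasts the median deviation before the intervention
week with the median after it:

    Delta = median(delta, before) - median(delta, after)

Positive ``Delta`` means pollution sat further below its counterfactual
after the intervention than before, i.e. a post-intervention decline.
Uncertainty comes from the bootstrap ensemble: the same contrast computed
against every replicate forecast path yields a percentile interval.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import CounterfactualForecast, DeviationSeries, InterventionEffect, ModelAssessment

logger = logging.getLogger(__name__)

__all__ = [
    "compute_deviations",
    "estimate_effect",
    "compute_ratio",
    "compute_ape",
    "compute_mase",
    "assess",
    "effects_table",
]


def compute_deviations(forecast: CounterfactualForecast) -> DeviationSeries:
    """Observed minus counterfactual, per week, with replicate-level detail."""
    return DeviationSeries(
        state=forecast.state,
        pollutant=forecast.pollutant,
        delta=forecast.c_obs - forecast.c_pred,
        replicate_delta=forecast.c_obs[None, :] - forecast.replicate_paths,
    )


def _split_windows(horizon: int, t_int_week: int) -> tuple[slice, slice]:
    """Before/after windows for a 1-based intervention week.

    The week containing the intervention date belongs to the "after"
    window (the intervention acts within that week), so before = weeks
    1..t-1 and after = weeks t..horizon.
    """
    if not 2 <= t_int_week <= horizon:
        raise ValueError(
            f"t_int_week {t_int_week} leaves an empty window (need 2..{horizon})"
        )
    return slice(0, t_int_week - 1), slice(t_int_week - 1, horizon)


def estimate_effect(
    dev: DeviationSeries, t_int_week: int, *, alpha: float = 0.05
) -> InterventionEffect:
    """Before/after median contrast with a bootstrap percentile interval.

    The interval is the ``alpha/2`` and ``1 - alpha/2`` percentiles of the
    contrast recomputed on each replicate's deviation series; the effect is
    flagged significant when the interval excludes zero.
    """
    before, after = _split_windows(dev.horizon, t_int_week)
    d_before = float(np.median(dev.delta[before]))
    d_after = float(np.median(dev.delta[after]))
    rep = dev.replicate_delta
    rep_delta = np.median(rep[:, before], axis=1) - np.median(rep[:, after], axis=1)
    ci_lo, ci_hi = np.percentile(rep_delta, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return InterventionEffect(
        state=dev.state,
        pollutant=dev.pollutant,
        t_int_week=int(t_int_week),
        delta_before=d_before,
        delta_after=d_after,
        delta=d_before - d_after,
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        significant=bool(ci_lo > 0 or ci_hi < 0),
    )


def compute_ratio(
    effect_no2: InterventionEffect, effect_pm25: InterventionEffect
) -> float:
    """Ratio of the NO2 effect to the PM2.5 effect for one state.

    Negative values mean the two pollutants moved in opposite directions.
    A zero PM2.5 effect makes the ratio undefined; NaN is returned (and
    logged) rather than raising, since downstream summaries simply skip
    undefined states.
    """
    if effect_pm25.delta == 0:
        logger.warning(
            "state %s: PM2.5 effect is exactly 0; ratio undefined", effect_pm25.state
        )
        return float("nan")
    return effect_no2.delta / effect_pm25.delta


def compute_ape(dev: DeviationSeries) -> float:
    """Average prediction error: the signed mean of the weekly deviations.

    Signed on purpose — over- and under-prediction cancel, so APE measures
    systematic displacement of observations from the counterfactual, in
    concentration units.
    """
    return float(np.mean(dev.delta))


def compute_mase(
    fitted: np.ndarray, actual: np.ndarray, training_actual: np.ndarray
) -> float:
    """Mean absolute scaled error against the one-step naive forecaster.

    ``mean|actual - fitted|`` scaled by the training-window mean absolute
    first difference (the naive forecaster's error). Values below 1 mean
    the model beats carrying yesterday's value forward. A constant
    training series has zero naive error; NaN is returned.
    """
    fitted = np.asarray(fitted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    training_actual = np.asarray(training_actual, dtype=float)
    if len(fitted) != len(actual):
        raise ValueError("fitted and actual must be aligned")
    if len(training_actual) < 2:
        raise ValueError("need >= 2 training observations for the naive scale")
    scale = np.mean(np.abs(np.diff(training_actual)))
    if scale == 0:
        logger.warning("constant training series: MASE undefined")
        return float("nan")
    return float(np.mean(np.abs(actual - fitted)) / scale)


def effects_table(effects) -> "pd.DataFrame":
    """Tabulate per-state effects in the ``effects.csv`` schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "state": e.state,
                "pollutant": e.pollutant,
                "t_int_week": e.t_int_week,
                "delta_before": e.delta_before,
                "delta_after": e.delta_after,
                "delta": e.delta,
                "ci_lo": e.ci_lo,
                "ci_hi": e.ci_hi,
                "significant": e.significant,
            }
            for e in effects
        ]
    )


def assess(
    dev: DeviationSeries,
    fitted_in_sample: np.ndarray,
    training_actual: np.ndarray,
) -> ModelAssessment:
    """Bundle APE (forecast window) and in-sample MASE for one state."""
    return ModelAssessment(
        state=dev.state,
        pollutant=dev.pollutant,
        ape=compute_ape(dev),
        mase=compute_mase(fitted_in_sample, training_actual, training_actual),
    )
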