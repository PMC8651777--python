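"""End-to-end glue: series -> counterfactual -> deviations -> effect."""

from __future__ import annotations

import numpy as np

from .counterfactual import OrderCaps, run_state
from .effects import compute_deviations, estimate_effect
from .types import CounterfactualForecast, DeviationSeries, InterventionEffect, WeeklySeries

__all__ = ["analyze_state"]


def analyze_state(
    series: WeeklySeries,
    t_int_week: int,
    *,
    B: int = 1000,
    m: int = 52,
    block_length: int = 24,
    caps: OrderCaps = OrderCaps(),
    seed: int | np.random.Generator | None = None,
) -> tuple[CounterfactualForecast, DeviationSeries, InterventionEffect]:
    """Counterfactual, deviations and before/after effect for one state.

    ``t_int_week`` is the 1-based forecast week containing the
    intervention (see :func:`airshift.io_weekly.week_index_of`); the
    forecasting stage itself never sees it.
    """
    forecast = run_state(
        series, B=B, m=m, block_length=block_length, caps=caps, seed=seed
    )
    dev = compute_deviations(forecast)
    effect = estimate_effect(dev, t_int_week)
    return forecast, dev, effect
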