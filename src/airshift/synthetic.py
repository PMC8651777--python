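"""Synthetic state-level pollution panels with known ground truth.

Generates the same objects the real pipeline consumes — weekly pollutant
series with aligned weather covariates, intervention weeks, and state
covariate tables — from a fully known generating process, so every
downstream stage (bootstrap, SARIMA counterfactual, effect estimation,
heterogeneity regression) can be checked by parameter recovery.

Generating process for one state's concentration series:

    Y_t = baseline + trend * t + amplitude * sin(2 pi t / period)
          + beta_weather . (W_t - mean(W))  + AR(p) noise
          - delta_true * 1[t in post-intervention forecast weeks]

floored at zero (concentrations are non-negative). The injected shift is
exactly ``delta_true`` relative to the no-intervention trajectory before
flooring, so recovery tests use baselines well above ``delta_true``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .heterogeneity import REGIONS, build_design
from .types import WEATHER_VARS, WeeklySeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "state_rng",
    "simulate_state_series",
    "simulate_panel",
    "simulate_state_covariates",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generating process.

    Defaults are desk-scale: a 12-week seasonal cycle (a "compressed
    year") keeps SARIMA fitting fast while exercising the same code paths
    as weekly data with ``seasonal_period=52``; five "years" of history
    plus a 16-week forecast window mirrors the real panel layout.
    Concentration units are generic (read ug/m3 for PM2.5, ppb for NO2).
    """

    n_states: int = 20
    n_years_history: int = 5
    seasonal_period: int = 12
    forecast_horizon: int = 16
    ar_coefs: tuple[float, ...] = (0.5,)
    seasonal_amplitude: float = 3.0
    trend_slope: float = -0.005
    baseline: float = 30.0
    weather_coefs: tuple[float, float, float] = (0.15, -0.1, 0.05)
    noise_sd: float = 1.0
    intervention_week: int = 9
    delta_true: float | Sequence[float] | None = None
    delta_range: tuple[float, float] = (1.0, 8.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_period < 2:
            raise ValueError("seasonal_period must be >= 2")
        if self.forecast_horizon < 2:
            raise ValueError("forecast_horizon must be >= 2")
        if not 1 < self.intervention_week < self.forecast_horizon:
            raise ValueError(
                "intervention_week must lie strictly inside (1, forecast_horizon) "
                "so both the before and after windows are non-empty"
            )
        if not self.noise_sd > 0 and self.noise_sd != 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("seasonal_amplitude", "trend_slope", "baseline", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("ar_coefs", "weather_coefs"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")

    @property
    def n_history(self) -> int:
        return self.n_years_history * self.seasonal_period

    @property
    def n_total(self) -> int:
        return self.n_history + self.forecast_horizon


@dataclass
class GroundTruth:
    """What the generator injected, for recovery tests."""

    delta_true: dict[str, float] = field(default_factory=dict)
    intervention_week: dict[str, int] = field(default_factory=dict)
    weather_coefs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    regression_coefs: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)


def state_rng(master_seed: int, state_id: str, stream: str = "series") -> np.random.Generator:
    """Deterministic per-state random stream.

    Sub-seeds come from a stable hash of ``(master_seed, state_id,
    stream)``, so states are reproducible individually and independent of
    each other and of generation order.
    """
    digest = hashlib.sha256(f"{master_seed}|{state_id}|{stream}".encode()).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest[:8], "big")))


def _ar_noise(ar_coefs: Sequence[float], sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(p) noise via a filtered Gaussian with burn-in."""
    if sd == 0:
        return np.zeros(n)
    p = len(ar_coefs)
    burn = max(10 * p, 50)
    eps = rng.normal(0.0, sd, n + burn)
    if p == 0 or not np.any(ar_coefs):
        return eps[burn:]
    return lfilter([1.0], np.r_[1.0, -np.asarray(ar_coefs, dtype=float)], eps)[burn:]


def _weather(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Smooth seasonal weather signals plus noise, one row per week."""
    t = np.arange(config.n_total, dtype=float)
    phase = 2 * np.pi * t / config.seasonal_period
    temperature = 15.0 + 10.0 * np.sin(phase) + rng.normal(0, 2.0, config.n_total)
    precipitation = np.maximum(
        0.0, 2.0 + 1.5 * np.sin(phase + np.pi / 3) + rng.normal(0, 1.0, config.n_total)
    )
    humidity = 60.0 + 15.0 * np.sin(phase + np.pi / 2) + rng.normal(0, 5.0, config.n_total)
    return pd.DataFrame(
        {"temperature": temperature, "precipitation": precipitation, "humidity": humidity}
    )


def _state_delta(config: SimulationConfig, state_index: int, state_id: str) -> float:
    if config.delta_true is None:
        rng = state_rng(config.master_seed, state_id, "delta")
        return float(rng.uniform(*config.delta_range))
    if np.isscalar(config.delta_true):
        return float(config.delta_true)
    return float(config.delta_true[state_index])


def simulate_state_series(
    config: SimulationConfig,
    state_id: str,
    *,
    state_index: int = 0,
    anchor: str | pd.Timestamp = "2020-01-01",
) -> tuple[WeeklySeries, dict]:
    """Generate one state's weekly series plus its ground-truth entry.

    The forecast period starts at ``anchor``; weeks at or after the
    state's intervention week (1-based within the forecast period) have
    their mean lowered by exactly ``delta_true``.
    """
    delta_true = _state_delta(config, state_index, state_id)
    if not np.isfinite(delta_true):
        raise ValueError("delta_true must be finite")
    rng = state_rng(config.master_seed, state_id, "series")
    n = config.n_total
    t = np.arange(n, dtype=float)

    weather = _weather(config, rng)
    w_centered = weather - weather.mean()
    weather_effect = w_centered.to_numpy() @ np.asarray(config.weather_coefs, dtype=float)

    latent = (
        config.baseline
        + config.trend_slope * t
        + config.seasonal_amplitude * np.sin(2 * np.pi * t / config.seasonal_period)
        + weather_effect
        + _ar_noise(config.ar_coefs, config.noise_sd, n, rng)
    )
    shift = np.zeros(n)
    post_start = config.n_history + (config.intervention_week - 1)
    shift[post_start:] = delta_true
    values = np.maximum(0.0, latent - shift)

    anchor = pd.Timestamp(anchor)
    week_start = anchor + pd.to_timedelta(
        7 * (np.arange(n) - config.n_history), unit="D"
    )
    series = WeeklySeries(
        state=state_id,
        pollutant="pm25",
        week_start=pd.DatetimeIndex(week_start),
        values=values,
        covariates=weather,
        split_index=config.n_history,
    )
    truth = {
        "state": state_id,
        "delta_true": delta_true,
        "intervention_week": config.intervention_week,
        "t_int_date": anchor + pd.Timedelta(days=7 * (config.intervention_week - 1)),
    }
    return series, truth


def simulate_panel(
    config: SimulationConfig, *, anchor: str | pd.Timestamp = "2020-01-01"
) -> tuple[list[WeeklySeries], GroundTruth]:
    """Generate ``config.n_states`` independent state series."""
    truth = GroundTruth(weather_coefs=tuple(config.weather_coefs))
    panel = []
    for i in range(config.n_states):
        state_id = f"S{i:02d}"
        series, entry = simulate_state_series(
            config, state_id, state_index=i, anchor=anchor
        )
        panel.append(series)
        truth.delta_true[state_id] = entry["delta_true"]
        truth.intervention_week[state_id] = entry["intervention_week"]
    return panel, truth


def simulate_state_covariates(
    n_states: int,
    regression_coefs: dict[str, float],
    het_sd_range: tuple[float, float] = (0.2, 1.5),
    *,
    master_seed: int = 0,
    dirichlet_alpha: tuple[float, float, float, float] = (1.0, 6.0, 5.0, 2.0),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """State covariate table plus effect outcomes from a known linear model.

    Source proportions (fire, stationary, mobile, biogenic) are drawn on
    the simplex and biogenic is dropped, mirroring how emissions-inventory
    shares enter the regression. Outcomes are generated from the design
    produced by :func:`airshift.heterogeneity.build_design` (main effects
    + all two-factor interactions) with coefficients looked up by term
    name (absent terms get 0), plus heteroscedastic Gaussian noise whose
    per-state SD is uniform on ``het_sd_range``.

    Returns ``(covariates, outcomes, true_noise_sd, design_matrix)``; the
    true SDs support inverse-variance weight construction in tests.
    """
    rng = state_rng(master_seed, "covariates", "table")
    props = rng.dirichlet(dirichlet_alpha, size=n_states)  # fire, stationary, mobile, biogenic
    density = rng.lognormal(mean=4.0, sigma=1.2, size=n_states)
    # cycle regions so every level keeps >= 2 states whenever n_states >= 8
    regions = [REGIONS[i % len(REGIONS)] for i in range(n_states)]
    covariates = pd.DataFrame(
        {
            "state": [f"S{i:02d}" for i in range(n_states)],
            "prop_fire": props[:, 0],
            "prop_stationary": props[:, 1],
            "prop_mobile": props[:, 2],
            "population_density": density,
            "region": regions,
        }
    ).set_index("state")

    design = build_design(covariates)
    if n_states <= design.n_params:
        raise ValueError(
            f"{n_states} states cannot identify {design.n_params} regression parameters"
        )
    beta = np.array([regression_coefs.get(term, 0.0) for term in design.X.columns])
    lo, hi = het_sd_range
    if lo < 0 or hi < lo:
        raise ValueError("het_sd_range must satisfy 0 <= lo <= hi")
    true_sd = rng.uniform(lo, hi, size=n_states)
    outcomes = design.X.to_numpy() @ beta + rng.normal(0.0, true_sd)
    return covariates, outcomes, true_sd, design.X
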