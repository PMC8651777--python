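"""Daily-to-weekly aggregation and panel IO.

Input tables arrive at daily x state resolution (monitor values already
averaged by day and state upstream). Weeks are 7-day half-open bins
``[anchor + 7k, anchor + 7(k+1))`` extending backward through the
training period and forward through the forecast period; the anchor is
the first day of the forecast period, so forecast weeks line up exactly
with the counterfactual horizon. A weekly value is the arithmetic mean of
the daily values present in its bin; empty bins are missing and may be
filled by short-gap linear interpolation (at most two consecutive weeks,
never at a series boundary).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import POLLUTANTS, WEATHER_VARS, InterventionCalendar, WeeklySeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_daily_tables",
    "aggregate_daily_to_weekly",
    "impute_short_gaps",
    "week_index_of",
    "write_weekly_panel",
    "read_weekly_panel",
]

_ALL_VARS = POLLUTANTS + WEATHER_VARS


def read_daily_tables(monitors_csv, weather_csv) -> pd.DataFrame:
    """Read monitor and weather CSVs into one long-format record table.

    ``monitors.csv`` has columns ``date,state,pollutant,value``;
    ``weather.csv`` has ``date,state,temperature,precipitation,humidity``.
    The result feeds :func:`aggregate_daily_to_weekly`.
    """
    monitors = pd.read_csv(monitors_csv)
    required = {"date", "state", "pollutant", "value"}
    if not required <= set(monitors.columns):
        raise ValueError(f"monitors table needs columns {sorted(required)}")
    monitors = monitors.rename(columns={"pollutant": "variable"})

    weather = pd.read_csv(weather_csv)
    required_w = {"date", "state"} | set(WEATHER_VARS)
    if not required_w <= set(weather.columns):
        raise ValueError(f"weather table needs columns {sorted(required_w)}")
    weather = weather.melt(
        id_vars=["date", "state"],
        value_vars=list(WEATHER_VARS),
        var_name="variable",
        value_name="value",
    )
    return pd.concat(
        [monitors[["date", "state", "variable", "value"]], weather],
        ignore_index=True,
    )


def _weekly_means(
    df: pd.DataFrame, anchor: pd.Timestamp
) -> pd.DataFrame:
    """Mean value per (state, variable, week index); week 0 starts at the anchor."""
    days = (pd.to_datetime(df["date"]) - anchor).dt.days
    out = df.assign(week=np.floor(days / 7).astype(int))
    return out.groupby(["state", "variable", "week"])["value"].mean()


def aggregate_daily_to_weekly(
    records: pd.DataFrame,
    week_anchor: str | pd.Timestamp,
    *,
    horizon: int = 16,
    max_gap: int = 2,
) -> dict[tuple[str, str], WeeklySeries]:
    """Aggregate long-format daily records to aligned state-week series.

    ``records`` has columns ``date, state, variable, value`` with
    variables among pollutant and weather names; ``week_anchor`` is the
    first day of the forecast period. Returns one :class:`WeeklySeries`
    per (state, pollutant) whose covariates are the state's weekly
    weather on the same bins, with short gaps linearly interpolated.

    Runs of more than ``max_gap`` consecutive missing weeks are a hard
    error naming the state and weeks: silent long imputation would
    manufacture training data.
    """
    required = {"date", "state", "variable", "value"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    bad = set(records["variable"].unique()) - set(_ALL_VARS)
    if bad:
        raise ValueError(f"unknown variables {sorted(bad)}; expected {_ALL_VARS}")
    values = records["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("records contain non-finite values")

    anchor = pd.Timestamp(week_anchor)
    means = _weekly_means(records, anchor)

    out: dict[tuple[str, str], WeeklySeries] = {}
    for state in sorted(records["state"].unique()):
        state_block = means.loc[state]
        first_week = min(idx[1] for idx in state_block.index)
        weeks = np.arange(first_week, horizon)
        index = pd.Index(weeks, name="week")
        cols = {}
        for var in _ALL_VARS:
            if var in state_block.index.get_level_values(0):
                cols[var] = state_block.loc[var].reindex(index)
        frame = pd.DataFrame(cols, index=index)
        week_dates = anchor + pd.to_timedelta(7 * weeks, unit="D")
        split = int((weeks < 0).sum())
        for pollutant in POLLUTANTS:
            if pollutant not in frame.columns:
                continue
            sub = pd.DataFrame(
                {"value": frame[pollutant]},
            )
            for w in WEATHER_VARS:
                sub[w] = frame[w] if w in frame.columns else np.nan
            filled = _fill_gaps(sub, state, max_gap=max_gap)
            out[(state, pollutant)] = WeeklySeries(
                state=state,
                pollutant=pollutant,
                week_start=pd.DatetimeIndex(week_dates),
                values=filled["value"].to_numpy(),
                covariates=filled[list(WEATHER_VARS)].reset_index(drop=True),
                split_index=split,
            )
    return out


def _gap_runs(isna: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of consecutive missing entries."""
    runs, start = [], None
    for i, m in enumerate(isna):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(isna) - start))
    return runs


def _fill_gaps(frame: pd.DataFrame, state: str, *, max_gap: int) -> pd.DataFrame:
    filled = frame.copy()
    for col in frame.columns:
        series = frame[col]
        runs = _gap_runs(series.isna().to_numpy())
        if not runs:
            continue
        for start, length in runs:
            if length > max_gap:
                weeks = list(series.index[start : start + length])
                raise ValueError(
                    f"state {state}, variable {col}: {length} consecutive missing "
                    f"weeks {weeks} exceed the {max_gap}-week imputation limit"
                )
            if start == 0 or start + length == len(series):
                raise ValueError(
                    f"state {state}, variable {col}: missing weeks at the series "
                    "boundary cannot be interpolated"
                )
        n_filled = int(series.isna().sum())
        filled[col] = series.interpolate(method="linear", limit_area="inside")
        logger.info("state %s %s: interpolated %d weekly values", state, col, n_filled)
    return filled


def impute_short_gaps(series: WeeklySeries, *, max_gap: int = 2) -> WeeklySeries:
    """Linearly interpolate interior gaps of at most ``max_gap`` weeks."""
    frame = pd.DataFrame({"value": series.values})
    for c in WEATHER_VARS:
        frame[c] = np.asarray(series.covariates[c], dtype=float)
    filled = _fill_gaps(frame, series.state, max_gap=max_gap)
    return WeeklySeries(
        state=series.state,
        pollutant=series.pollutant,
        week_start=series.week_start,
        values=filled["value"].to_numpy(),
        covariates=filled[list(WEATHER_VARS)],
        split_index=series.split_index,
    )


def week_index_of(
    calendar: InterventionCalendar, series: WeeklySeries, state: str | None = None
) -> int:
    """1-based forecast week containing the state's intervention date.

    The week containing the date belongs to the "after" window downstream,
    so the before window is weeks ``1..i-1``. Errors if the date falls
    outside the forecast period.
    """
    state = state or series.state
    if state not in calendar.emergency_date:
        raise KeyError(f"no intervention date for state {state}")
    t_int = calendar.emergency_date[state]
    start = series.forecast_week_start[0]
    days = (t_int - start).days
    idx = days // 7 + 1
    if not 1 <= idx <= series.horizon:
        raise ValueError(
            f"intervention date {t_int.date()} outside the forecast period "
            f"({start.date()} + {series.horizon} weeks) for state {state}"
        )
    return int(idx)


def write_weekly_panel(series_map: dict, path) -> None:
    """Write a collection of weekly series to ``weekly_panel.csv``."""
    frames = [s.to_frame() for s in series_map.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_weekly_panel(path) -> dict[tuple[str, str], WeeklySeries]:
    """Inverse of :func:`write_weekly_panel`."""
    df = pd.read_csv(path)
    out = {}
    for (state, pollutant), block in df.groupby(["state", "pollutant"]):
        out[(str(state), str(pollutant))] = WeeklySeries.from_frame(block)
    return out
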