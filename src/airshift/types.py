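"""Core containers shared across the pipeline.

The unit of analysis is one state x pollutant weekly concentration series
with aligned meteorological covariates, split into a multi-year training
window and a short forecast window in which an intervention may fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WEATHER_VARS = ("temperature", "precipitation", "humidity")
POLLUTANTS = ("pm25", "no2")


@dataclass
class WeeklySeries:
    """One state x pollutant weekly series with aligned weather covariates.

    Parameters
    ----------
    state : str
        Two-letter state code (or any label for synthetic states).
    pollutant : str
        ``"pm25"`` (ug/m3) or ``"no2"`` (ppb).
    week_start : pd.DatetimeIndex
        Start date of each 7-day bin; strictly increasing at 7-day spacing.
    values : np.ndarray
        Weekly mean concentrations, one per week.
    covariates : pd.DataFrame
        Columns ``temperature``, ``precipitation``, ``humidity``; one row
        per week, positionally aligned with ``values``.
    split_index : int
        Number of training weeks; weeks ``[split_index:]`` form the
        forecast period.
    """

    state: str
    pollutant: str
    week_start: pd.DatetimeIndex
    values: np.ndarray
    covariates: pd.DataFrame
    split_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.week_start = pd.DatetimeIndex(self.week_start)
        n = len(self.values)
        if len(self.week_start) != n or len(self.covariates) != n:
            raise ValueError(
                f"length mismatch: {n} values, {len(self.week_start)} weeks, "
                f"{len(self.covariates)} covariate rows"
            )
        if n >= 2:
            gaps = np.diff(self.week_start.values).astype("timedelta64[D]")
            if not (gaps == np.timedelta64(7, "D")).all():
                raise ValueError("week_start must be strictly increasing at 7-day spacing")
        if not 0 < self.split_index < n:
            raise ValueError(f"split_index {self.split_index} outside (0, {n})")
        missing = [c for c in WEATHER_VARS if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariates missing columns {missing}")

    @property
    def n_weeks(self) -> int:
        return len(self.values)

    @property
    def horizon(self) -> int:
        """Number of forecast-period weeks."""
        return self.n_weeks - self.split_index

    @property
    def train_values(self) -> np.ndarray:
        return self.values[: self.split_index]

    @property
    def forecast_values(self) -> np.ndarray:
        """Observed concentrations during the forecast period."""
        return self.values[self.split_index :]

    @property
    def train_covariates(self) -> pd.DataFrame:
        return self.covariates.iloc[: self.split_index]

    @property
    def forecast_covariates(self) -> pd.DataFrame:
        return self.covariates.iloc[self.split_index :]

    @property
    def forecast_week_start(self) -> pd.DatetimeIndex:
        return self.week_start[self.split_index :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table matching the ``weekly_panel.csv`` schema."""
        df = pd.DataFrame(
            {
                "state": self.state,
                "pollutant": self.pollutant,
                "week_start": self.week_start.strftime("%Y-%m-%d"),
                "value": self.values,
            }
        )
        for c in WEATHER_VARS:
            df[c] = np.asarray(self.covariates[c], dtype=float)
        df["is_forecast_period"] = np.arange(self.n_weeks) >= self.split_index
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeeklySeries":
        """Inverse of :meth:`to_frame` for a single state x pollutant block."""
        states = df["state"].unique()
        pollutants = df["pollutant"].unique()
        if len(states) != 1 or len(pollutants) != 1:
            raise ValueError("from_frame expects a single state x pollutant block")
        df = df.sort_values("week_start").reset_index(drop=True)
        split = int((~df["is_forecast_period"].astype(bool)).sum())
        return cls(
            state=str(states[0]),
            pollutant=str(pollutants[0]),
            week_start=pd.DatetimeIndex(pd.to_datetime(df["week_start"])),
            values=df["value"].to_numpy(dtype=float),
            covariates=df[list(WEATHER_VARS)].reset_index(drop=True),
            split_index=split,
        )


@dataclass
class InterventionCalendar:
    """Per-state intervention dates (state-of-emergency declarations).

    ``emergency_date`` drives the before/after split; additional policy
    dates may be carried for reporting but are not used by the estimator.
    """

    emergency_date: dict[str, pd.Timestamp]
    other_dates: dict[str, dict[str, pd.Timestamp]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emergency_date = {
            str(k): pd.Timestamp(v) for k, v in self.emergency_date.items()
        }

    @classmethod
    def from_csv(cls, path) -> "InterventionCalendar":
        df = pd.read_csv(path)
        if "state" not in df.columns or "emergency_date" not in df.columns:
            raise ValueError("interventions table needs columns state, emergency_date")
        emergency = dict(zip(df["state"].astype(str), pd.to_datetime(df["emergency_date"])))
        extra_cols = [c for c in df.columns if c not in ("state", "emergency_date")]
        other: dict[str, dict[str, pd.Timestamp]] = {}
        for _, row in df.iterrows():
            extras = {
                c: pd.Timestamp(row[c]) for c in extra_cols if pd.notna(row[c])
            }
            if extras:
                other[str(row["state"])] = extras
        return cls(emergency_date=emergency, other_dates=other)


@dataclass
class CounterfactualForecast:
    """Bagged counterfactual forecast for one state x pollutant.

    ``replicate_paths`` holds one forecast path per surviving bootstrap
    replicate; ``c_pred`` is their pointwise mean and the bands are
    empirical 2.5/97.5 percentiles across replicates.
    """

    state: str
    pollutant: str
    week_start: pd.DatetimeIndex
    replicate_paths: np.ndarray  # (n_surviving, horizon)
    c_pred: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    c_obs: np.ndarray
    n_requested: int

    def __post_init__(self) -> None:
        self.replicate_paths = np.atleast_2d(np.asarray(self.replicate_paths, dtype=float))
        h = self.replicate_paths.shape[1]
        for name in ("c_pred", "lo95", "hi95", "c_obs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (h,):
                raise ValueError(f"{name} must have length {h}")
            setattr(self, name, arr)

    @property
    def n_surviving(self) -> int:
        return self.replicate_paths.shape[0]

    @property
    def horizon(self) -> int:
        return self.replicate_paths.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.state,
                "pollutant": self.pollutant,
                "week_start": self.week_start.strftime("%Y-%m-%d"),
                "c_obs": self.c_obs,
                "c_pred": self.c_pred,
                "lo95": self.lo95,
                "hi95": self.hi95,
                "n_replicates_surviving": self.n_surviving,
            }
        )


@dataclass
class DeviationSeries:
    """Weekly deviations delta_i = observed minus bagged counterfactual."""

    state: str
    pollutant: str
    delta: np.ndarray  # (horizon,)
    replicate_delta: np.ndarray  # (n_surviving, horizon): obs - each replicate path

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.replicate_delta = np.atleast_2d(np.asarray(self.replicate_delta, dtype=float))
        if self.replicate_delta.shape[1] != len(self.delta):
            raise ValueError("replicate deviations misaligned with bagged deviations")

    @property
    def horizon(self) -> int:
        return len(self.delta)


@dataclass
class InterventionEffect:
    """Before/after contrast of weekly deviations for one state.

    ``delta = delta_before - delta_after`` where each term is the median
    weekly deviation in its window; positive values indicate a
    post-intervention decline under this package's sign convention.
    """

    state: str
    pollutant: str
    t_int_week: int
    delta_before: float
    delta_after: float
    delta: float
    ci_lo: float
    ci_hi: float
    significant: bool

    def __post_init__(self) -> None:
        if not np.isclose(self.delta, self.delta_before - self.delta_after):
            raise ValueError("delta must equal delta_before - delta_after")


@dataclass
class ModelAssessment:
    """Forecast-period mean signed error (APE) and in-sample MASE."""

    state: str
    pollutant: str
    ape: float
    mase: float
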