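"""Bootstrap replication of a weekly series.

A training series is Box-Cox transformed, split additively into trend,
seasonal and remainder components with STL, and the remainder is resampled
with a moving-block bootstrap (MBB). Re-assembling trend + seasonal +
resampled remainder and inverting the transform yields replicate series
that preserve the trend, the seasonal cycle, and the short-range
autocorrelation of the remainder. Fitting the forecasting model to each
replicate and averaging the forecasts ("bagging") both stabilises the
point forecast and yields an empirical forecast distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import boxcox as _boxcox, inv_boxcox as _inv_boxcox
from statsmodels.tsa.seasonal import STL

logger = logging.getLogger(__name__)

__all__ = [
    "Decomposition",
    "BootstrapEnsemble",
    "guerrero_lambda",
    "boxcox_transform",
    "inverse_boxcox_transform",
    "stl_decompose",
    "moving_block_resample",
    "generate_ensemble",
]


@dataclass
class Decomposition:
    """Additive decomposition of a (transformed) series.

    ``trend + seasonal + remainder`` reconstructs the transformed series
    exactly; ``lmbda`` and ``offset`` record the Box-Cox transform that
    produced it (``lmbda=None`` when the decomposition was run on the raw
    scale).
    """

    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    lmbda: float | None = None
    offset: float = 0.0

    def reconstruct(self) -> np.ndarray:
        return self.trend + self.seasonal + self.remainder


@dataclass
class BootstrapEnsemble:
    """B resampled versions of one training series."""

    replicates: np.ndarray  # (B, n)
    block_length: int
    seed: int | None
    lmbda: float

    @property
    def B(self) -> int:
        return self.replicates.shape[0]

    @property
    def n_weeks(self) -> int:
        return self.replicates.shape[1]

    def to_frame(self, week_start=None):
        """Long-format table (replicate_id, week_start, value) for audit/restart."""
        import pandas as pd

        if week_start is None:
            week_start = np.arange(self.n_weeks)
        rep_id = np.repeat(np.arange(self.B), self.n_weeks)
        return pd.DataFrame(
            {
                "replicate_id": rep_id,
                "week_start": np.tile(np.asarray(week_start), self.B),
                "value": self.replicates.ravel(),
            }
        )


def guerrero_lambda(x: np.ndarray, period: int) -> float:
    """Select a Box-Cox lambda by Guerrero's method, clamped to [0, 1].

    The series is cut into consecutive length-``period`` subseries; lambda
    minimises the coefficient of variation of ``sd_h / mean_h**(1-lambda)``
    across subseries, i.e. it decouples subseries spread from level.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Guerrero lambda selection requires a strictly positive series")
    n_sub = len(x) // period
    if n_sub < 2:
        return 1.0  # too short to estimate; leave the scale alone
    chunks = x[: n_sub * period].reshape(n_sub, period)
    means = chunks.mean(axis=1)
    sds = chunks.std(axis=1, ddof=1)

    def cv(lmbda: float) -> float:
        ratio = sds / means ** (1.0 - lmbda)
        m = ratio.mean()
        if m == 0:
            return np.inf
        return ratio.std(ddof=1) / m

    res = minimize_scalar(cv, bounds=(0.0, 1.0), method="bounded")
    return float(np.clip(res.x, 0.0, 1.0))


def _positivity_offset(x: np.ndarray) -> float:
    """Offset making a series strictly positive: half the smallest positive value."""
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("series has no positive values; cannot choose a Box-Cox offset")
    return float(pos.min() / 2.0)


def boxcox_transform(
    x: np.ndarray,
    lmbda: float | None = None,
    period: int | None = None,
    offset: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform ``(x^lambda - 1) / lambda`` (log at lambda=0).

    If ``lmbda`` is None it is estimated by :func:`guerrero_lambda`
    (``period`` then required). Non-positive values are shifted by an
    offset (half the smallest positive observation unless given).

    Returns ``(transformed, lmbda, offset)``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if offset is None:
        offset = _positivity_offset(x) if np.any(x <= 0) else 0.0
    shifted = x + offset
    if np.any(shifted <= 0):
        raise ValueError("series not strictly positive after offset")
    if lmbda is None:
        if period is None:
            raise ValueError("period required to estimate lambda")
        lmbda = guerrero_lambda(shifted, period)
    return _boxcox(shifted, lmbda), float(lmbda), float(offset)


def inverse_boxcox_transform(
    y: np.ndarray, lmbda: float, offset: float = 0.0
) -> np.ndarray:
    """Inverse Box-Cox; arguments outside the transform's range are clamped.

    For lambda > 0 the forward transform maps (0, inf) to
    (-1/lambda, inf); resampled remainders can step just below that
    floor, so the argument is clamped to keep the inverse finite.
    """
    y = np.asarray(y, dtype=float)
    if lmbda != 0:
        floor = -1.0 / lmbda + 1e-12 if lmbda > 0 else -np.inf
        y = np.maximum(y, floor)
    return _inv_boxcox(y, lmbda) - offset


def stl_decompose(
    x: np.ndarray, period: int, seasonal_window: int | None = None
) -> Decomposition:
    """STL decomposition with an (effectively) periodic seasonal component.

    ``seasonal_window`` is the Loess window for the seasonal smoother, in
    cycles; by default it is very large, so the seasonal pattern is close
    to periodic across years (pollutant seasonality is treated as stable
    over a five-year training window).
    """
    x = np.asarray(x, dtype=float)
    if period < 2:
        raise ValueError("period must be >= 2")
    if len(x) < 2 * period:
        raise ValueError(f"series length {len(x)} < 2 x period {period}")
    if seasonal_window is None:
        seasonal_window = 999  # >> series length: near-periodic seasonality
    if seasonal_window % 2 == 0:
        seasonal_window += 1
    fit = STL(x, period=period, seasonal=seasonal_window, robust=False).fit()
    return Decomposition(
        trend=np.asarray(fit.trend),
        seasonal=np.asarray(fit.seasonal),
        remainder=np.asarray(fit.resid),
    )


def moving_block_resample(
    remainder: np.ndarray, block_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Moving-block bootstrap of a (roughly stationary) remainder series.

    Contiguous blocks of ``block_length`` are drawn uniformly with
    replacement from all overlapping start positions and concatenated;
    a random initial offset is discarded and the result trimmed to the
    input length. ``block_length == n`` degenerates to the identity
    (only one block exists and no offset is discarded).
    """
    remainder = np.asarray(remainder, dtype=float)
    n = len(remainder)
    if not 1 <= block_length <= n:
        raise ValueError(f"block_length {block_length} outside [1, {n}]")
    if block_length == n:
        return remainder.copy()
    n_positions = n - block_length + 1
    n_blocks = n // block_length + 2  # enough to cover n after the offset
    starts = rng.integers(0, n_positions, size=n_blocks)
    blocks = [remainder[s : s + block_length] for s in starts]
    concat = np.concatenate(blocks)
    offset = int(rng.integers(0, block_length))
    return concat[offset : offset + n]


def generate_ensemble(
    series: np.ndarray,
    B: int,
    period: int,
    block_length: int = 24,
    seed: int | np.random.Generator | None = None,
    include_original: bool = True,
    lmbda: float | None = None,
    seasonal_window: int | None = None,
) -> BootstrapEnsemble:
    """Generate ``B`` bootstrap replicates of a weekly training series.

    Each replicate is ``inverse-BoxCox(trend + seasonal + MBB(remainder))``.
    With ``include_original`` the first replicate is the untouched input,
    so the original series always contributes one forecast path to the bag.
    """
    series = np.asarray(series, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    transformed, lam, offset = boxcox_transform(series, lmbda=lmbda, period=period)
    dec = stl_decompose(transformed, period, seasonal_window=seasonal_window)
    base = dec.trend + dec.seasonal
    block_length = min(block_length, len(series))
    replicates = np.empty((B, len(series)))
    start = 0
    if include_original:
        replicates[0] = series
        start = 1
    for b in range(start, B):
        resampled = moving_block_resample(dec.remainder, block_length, rng)
        replicates[b] = inverse_boxcox_transform(base + resampled, lam, offset)
    logger.debug("generated %d replicates (lambda=%.3f, block=%d)", B, lam, block_length)
    return BootstrapEnsemble(
        replicates=replicates,
        block_length=block_length,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        lmbda=lam,
    )
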