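"""Trend / fluctuation separation for sensor time series.

The additive model ``F(t) = Trend(t) + Fluctuations(t)`` is realized either
by seasonal detrending — a centered moving average with filtering window
``f`` (hours) — or by empirical mode decomposition, keeping all but the last
``m`` (fastest) modes for the trend.

Both detrenders follow the scikit-learn transformer protocol: ``fit`` learns
the decomposition of a 1-D signal, ``transform`` returns the fluctuation
component, and fitted attributes (``trend_``, ``fluctuations_``) expose the
pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .emd import IMFSet, emd
from .timeseries import TimeSeries

__all__ = [
    "DecompositionResult",
    "SeasonalDetrender",
    "EMDDetrender",
    "seasonal_decompose",
    "partition_modes",
]


@dataclass
class DecompositionResult:
    """Additive trend/fluctuation split of one series.

    ``trend + fluctuations`` reproduces the input wherever both are defined;
    entries where the trend is undefined (moving-average edge trim) are NaN.
    """

    trend: np.ndarray
    fluctuations: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        """Boolean mask of samples where both components are defined."""
        return np.isfinite(self.trend) & np.isfinite(self.fluctuations)


def _as_values(X) -> np.ndarray:
    if isinstance(X, TimeSeries):
        return np.asarray(X.values, dtype=float)
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:  # sklearn-style column vector
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal or a single-column array")
    return x


def _ma_weights(window: int) -> np.ndarray:
    if window % 2 == 1:
        w = np.full(window, 1.0 / window)
    else:
        w = np.r_[0.5, np.ones(window - 1), 0.5] / window
    return w


def _moving_average_trend(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; even windows use the standard 2xMA so the
    filter stays centered (weights 1/2, 1, ..., 1, 1/2 over window+1 points).
    This is the same filter statsmodels' seasonal decomposition applies."""
    n = len(x)
    if window > n:
        raise ValueError(f"moving-average window {window} longer than series {n}")
    w = _ma_weights(window)
    half = len(w) // 2
    trend = np.full(n, np.nan)
    core = np.convolve(x, w, mode="valid")
    trend[half : half + len(core)] = core
    return trend


class SeasonalDetrender(BaseEstimator, TransformerMixin):
    """Detrend by a centered moving average with window ``f_hours``.

    Parameters
    ----------
    f_hours : float, default 6
        Filtering window in hours; 6 h is the working default for 15-minute
        water-quality records.
    step_minutes : float, default 15
        Sampling interval used to convert ``f_hours`` into samples.
    """

    def __init__(self, f_hours: float = 6.0, step_minutes: float = 15.0):
        self.f_hours = f_hours
        self.step_minutes = step_minutes

    def fit(self, X, y=None):
        x = _as_values(X)
        window = int(round(self.f_hours * 60.0 / self.step_minutes))
        if window < 2:
            raise ValueError("filtering window must span at least 2 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("seasonal detrending requires a gap-free span")
        self.window_samples_ = window
        self.filter_weights_ = _ma_weights(window)
        self.trend_ = _moving_average_trend(x, window)
        self.fluctuations_ = x - self.trend_
        self.n_samples_ = len(x)
        return self

    def transform(self, X):
        """Return the fluctuation component of ``X`` (refit on new data)."""
        self.fit(X)
        return self.fluctuations_

    def result_(self) -> DecompositionResult:
        return DecompositionResult(
            trend=self.trend_,
            fluctuations=self.fluctuations_,
            method="seasonal",
            params={"f_hours": self.f_hours, "window_samples": self.window_samples_},
        )


class EMDDetrender(BaseEstimator, TransformerMixin):
    """Detrend by empirical mode decomposition, assigning the ``m`` fastest
    modes to the fluctuations and the rest to the trend.

    The decomposition is carried out on the full record in one pass; ``m``
    can be changed after fitting without re-sifting via
    :meth:`partition`.
    """

    def __init__(
        self,
        m: int = 2,
        max_imfs: int = 12,
        sd_threshold: float = 0.2,
        max_sift_iterations: int = 12,
    ):
        self.m = m
        self.max_imfs = max_imfs
        self.sd_threshold = sd_threshold
        self.max_sift_iterations = max_sift_iterations

    def fit(self, X, y=None):
        x = _as_values(X)
        self.imfs_ = emd(
            x,
            max_imfs=self.max_imfs,
            sd_threshold=self.sd_threshold,
            max_sift_iterations=self.max_sift_iterations,
        )
        result = partition_modes(self.imfs_, self.m)
        self.trend_ = result.trend
        self.fluctuations_ = result.fluctuations
        self.n_samples_ = len(x)
        return self

    def transform(self, X):
        self.fit(X)
        return self.fluctuations_

    def partition(self, m: int) -> DecompositionResult:
        """Re-partition the already-sifted modes with a different ``m``."""
        return partition_modes(self.imfs_, m)

    def result_(self) -> DecompositionResult:
        return partition_modes(self.imfs_, self.m)


def seasonal_decompose(
    series, f_hours: float = 6.0, step_minutes: float | None = None
) -> DecompositionResult:
    """Functional form of :class:`SeasonalDetrender`."""
    if step_minutes is None:
        step_minutes = series.step_minutes if isinstance(series, TimeSeries) else 15.0
    det = SeasonalDetrender(f_hours=f_hours, step_minutes=step_minutes).fit(series)
    return det.result_()


def partition_modes(imfs: IMFSet, m: int) -> DecompositionResult:
    """Split modes into trend (slowest ``N - m``) and fluctuations (fastest
    ``m``); with modes ordered slowest first this keeps the leading modes as
    trend."""
    n = imfs.n_modes
    if not 0 <= m <= n:
        raise ValueError(f"m={m} outside [0, {n}]")
    trend = imfs.modes[: n - m].sum(axis=0) if m < n else np.zeros(imfs.modes.shape[1])
    fluct = imfs.modes[n - m :].sum(axis=0) if m > 0 else np.zeros(imfs.modes.shape[1])
    return DecompositionResult(
        trend=trend,
        fluctuations=fluct,
        method="emd",
        params={"m": m, "n_modes": n},
    )
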