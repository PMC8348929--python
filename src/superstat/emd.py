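"""Empirical mode decomposition by iterative sifting.

The signal is decomposed into intrinsic mode functions (IMFs) by repeatedly
subtracting the mean of cubic-spline envelopes through local maxima and
minima. Boundaries are handled by mirror-symmetric extension of the extrema;
sifting of one mode stops on a Cauchy-type criterion
``sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold`` or after a fixed
iteration cap. The final residual (the slowest component) is stored as a
mode, so the modes sum exactly to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["IMFSet", "emd"]


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions, slowest first.

    ``modes[0]`` is the residual/trend-like component and ``modes[-1]`` the
    fastest oscillation; summing all modes restores the input signal.
    """

    modes: np.ndarray  # shape (n_modes, n_samples), slowest first
    sift_meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.modes.sum(axis=0)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima, with plateau midpoints."""
    dx = np.diff(x)
    # sign of slope, carrying the previous sign across flat segments
    s = np.sign(dx)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    turns = np.diff(s)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int, n_pad: int = 2):
    """Mirror extrema about both signal endpoints to anchor the envelopes."""
    k = min(n_pad, len(idx))
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    ii = np.r_[left_i, idx, right_i]
    vv = np.r_[left_v, val, right_v]
    order = np.argsort(ii, kind="stable")
    ii, vv = ii[order], vv[order]
    keep = np.r_[True, np.diff(ii) > 0]
    return ii[keep], vv[keep]


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n = len(x)
    ii, vv = _mirror_extend(idx, x[idx], n)
    if len(ii) < 2:
        return np.full(n, vv[0] if len(vv) else 0.0)
    if len(ii) < 4:
        return np.interp(np.arange(n), ii, vv)
    return CubicSpline(ii, vv)(np.arange(n))


def _sift_once(h: np.ndarray) -> tuple[np.ndarray, int]:
    maxima, minima = _local_extrema(h)
    n_ext = len(maxima) + len(minima)
    if len(maxima) < 2 or len(minima) < 2:
        return h, n_ext
    upper = _envelope(h, maxima)
    lower = _envelope(h, minima)
    return h - 0.5 * (upper + lower), n_ext


def emd(
    values: np.ndarray,
    max_imfs: int = 12,
    sd_threshold: float = 0.2,
    max_sift_iterations: int = 12,
) -> IMFSet:
    """Decompose a gap-free signal into IMFs plus a residual.

    Parameters
    ----------
    values : array-like
        Uniformly sampled signal, at least 16 samples, no NaN.
    max_imfs : int
        Cap on the number of oscillatory modes extracted.
    sd_threshold : float
        Cauchy stopping threshold for the sifting of each mode.
    max_sift_iterations : int
        Iteration cap per mode.

    Returns
    -------
    IMFSet
        Modes ordered slowest first; their sum equals the input to floating
        point accuracy because the residual is included as the first mode.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if len(x) < 16:
        raise ValueError("emd needs at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("emd input must be gap-free (no NaN/inf)")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    iterations: list[int] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 2:
            break  # residual is monotone-like: stop
        h = residual.copy()
        n_iter = 0
        for n_iter in range(1, max_sift_iterations + 1):
            h_new, n_ext = _sift_once(h)
            if n_ext < 4:
                h = h_new
                break
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        iterations.append(n_iter)
        residual = residual - h
        if np.max(np.abs(residual)) < 1e-12 * max(np.max(np.abs(x)), 1e-300):
            break

    # slowest first: residual, then IMFs from slowest to fastest
    modes = np.vstack([residual] + imfs[::-1]) if imfs else residual[None, :]
    return IMFSet(
        modes=modes,
        sift_meta={
            "sd_threshold": sd_threshold,
            "max_sift_iterations": max_sift_iterations,
            "iterations_per_mode": iterations,
        },
    )
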