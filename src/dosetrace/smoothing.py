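"""Gaussian-kernel dose-curve smoothing and its summary statistics.

Each trace is smoothed with a Nadaraya-Watson estimator using a Gaussian
kernel on the ordinal dose positions: for every evaluation point x_i the
fitted value is the weighted mean of all observations,

    d_k  = (x_k - x_i) / b
    wt_k = exp(-d_k^2 / 2) / sqrt(2 pi)
    yhat_i = sum_k wt_k * y_k / sum_k wt_k,

with the point itself included in its own average (d = 0). No parametric
(sigmoidal) model and no goodness-of-fit gate is applied anywhere: the
single-number response metric is the *average slope*, the mean of the
slopes of adjacent fitted points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError
from .io import RunConfig
from .preprocess import DoseTrace

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class FittedCurve:
    """A smoothed dose trace with its derived statistics.

    ``max_up_run`` / ``max_down_run`` count the longest runs of strictly
    increasing / strictly decreasing adjacent fitted pairs; equal adjacent
    fitted values terminate both kinds of run.
    """

    x: tuple[int, ...]
    y: tuple[float, ...]
    y_hat: tuple[float, ...]
    bandwidth: float
    average_slope: float
    range_fitted: float
    max_up_run: int
    max_down_run: int
    end_diff: float


def kernel_weights(x: np.ndarray, b: float) -> np.ndarray:
    """The n x n Gaussian weight matrix W[i, k] = phi((x_k - x_i)/b)."""
    d = (x[None, :] - x[:, None]) / b
    return np.exp(-0.5 * d * d) / _SQRT2PI


def gaussian_kernel_smooth(x, y, b: float) -> np.ndarray:
    """Smooth ``y`` observed at positions ``x`` with bandwidth ``b``.

    Every fitted value is a convex combination of the observations, so
    min(y) <= yhat_i <= max(y) holds for all i.
    """
    if b <= 0:
        raise ConfigError(f"bandwidth must be > 0, got {b}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InputError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise InputError(f"need at least 3 points to smooth, got {len(x)}")
    if np.any(np.diff(x) <= 0):
        raise InputError("x must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise InputError("y contains NaN or infinite values")
    w = kernel_weights(x, b)
    # centring on y[0] keeps constant traces exact fixed points in floating
    # point (the weighted mean of an all-zero vector is exactly zero)
    return y[0] + (w @ (y - y[0])) / w.sum(axis=1)


def average_slope(y_hat, x) -> float:
    """Mean slope of adjacent fitted points: mean_i of dyhat_i / dx_i.

    On an equally spaced grid this telescopes to
    (yhat_last - yhat_first) / (n - 1) / spacing.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y_hat) < 2 or len(x) != len(y_hat):
        raise InputError("average_slope needs >= 2 points with matching x")
    return float(np.mean(np.diff(y_hat) / np.diff(x)))


def run_statistics(y_hat) -> tuple[int, int]:
    """Longest strictly-increasing and strictly-decreasing runs of adjacent
    pairs. Ties (equal adjacent values) break both runs."""
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y_hat) < 2:
        raise InputError("run_statistics needs >= 2 points")
    diffs = np.diff(y_hat)
    max_up = max_down = up = down = 0
    for d in diffs:
        up = up + 1 if d > 0 else 0
        down = down + 1 if d < 0 else 0
        max_up = max(max_up, up)
        max_down = max(max_down, down)
    return max_up, max_down


def fit_curve(x, y, b: float) -> FittedCurve:
    """Smooth one normalized trace and populate all curve statistics."""
    y_hat = gaussian_kernel_smooth(x, y, b)
    max_up, max_down = run_statistics(y_hat)
    return FittedCurve(
        x=tuple(int(v) for v in x),
        y=tuple(float(v) for v in y),
        y_hat=tuple(float(v) for v in y_hat),
        bandwidth=float(b),
        average_slope=average_slope(y_hat, x),
        range_fitted=float(np.max(y_hat) - np.min(y_hat)),
        max_up_run=max_up,
        max_down_run=max_down,
        end_diff=float(abs(y_hat[-1] - y_hat[0])),
    )


def fit_trace(trace: DoseTrace, config: RunConfig) -> FittedCurve:
    """Fit a preprocessed (normalized) dose trace under the run config."""
    if not trace.normalized:
        raise InputError(f"{trace.entity_id}: trace must be normalized before fitting")
    return fit_curve(trace.x, trace.y, config.bandwidth)
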