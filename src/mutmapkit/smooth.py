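"""Locally weighted scatterplot smoothing (LOWESS) with batch support.

Cleveland's estimator: at each point, a weighted linear regression over the
``span_fraction`` nearest neighbours with tricube weights, optionally
followed by bisquare robustness reweighting passes. The implementation is
vectorised over many tracks sharing one abscissa, which is what the
null-threshold simulation needs (hundreds of replicate tracks smoothed
identically); memory is O(n^2) in the number of points, so callers smooth
per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SmoothingParams", "lowess_smooth", "lowess_batch"]


@dataclass(frozen=True)
class SmoothingParams:
    """span_fraction: fraction of points in each local window;
    robustness_iterations: bisquare reweighting passes (Cleveland's default 3)."""

    span_fraction: float = 0.05
    robustness_iterations: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.span_fraction <= 1):
            raise ValueError("span_fraction must be in (0, 1]")
        if self.robustness_iterations < 0:
            raise ValueError("robustness_iterations must be >= 0")


def _tricube_matrix(x: np.ndarray, span_fraction: float) -> np.ndarray:
    """Dense (n, n) tricube neighbourhood weights, row i = window around x_i."""
    n = x.size
    k = min(n, max(2, int(span_fraction * n)))
    dist = np.abs(x[:, None] - x[None, :])
    # distance to the k-th nearest neighbour (self included)
    d_max = np.partition(dist, k - 1, axis=1)[:, k - 1]
    d_max = np.where(d_max > 0, d_max, 1.0)  # degenerate window: equal weights at dist 0
    u = np.clip(dist / d_max[:, None], 0.0, 1.0)
    return (1.0 - u**3) ** 3


def lowess_batch(x: np.ndarray, Y: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Smooth every row of ``Y`` (m, n) against the shared, strictly
    increasing abscissa ``x`` (n,). Returns an (m, n) array."""
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    if Y.shape[1] != n:
        raise ValueError("Y and x length mismatch")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing (average ties first)")
    if n == 1:
        return Y.copy()

    # standardise the abscissa; lowess is invariant under affine maps of x
    xs = (x - x.mean()) / x.std()
    W = _tricube_matrix(xs, params.span_fraction)
    Wt = W.T.copy()
    delta = np.ones_like(Y)

    fitted = np.empty_like(Y)
    for _ in range(params.robustness_iterations + 1):
        sw = delta @ Wt
        swx = (delta * xs) @ Wt
        swxx = (delta * xs * xs) @ Wt
        swy = (delta * Y) @ Wt
        swxy = (delta * Y * xs) @ Wt
        denom = swxx - swx * swx / sw
        slope = np.where(denom > 1e-12, (swxy - swx * swy / sw) / np.where(denom > 0, denom, 1.0), 0.0)
        fitted = (swy - slope * swx) / sw + slope * xs[None, :]
        resid = np.abs(Y - fitted)
        s = np.median(resid, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(s > 0, resid / (6.0 * s), 0.0)
        # the floor keeps local weight sums nonzero when bisquare zeroes a
        # whole window (degenerate near-exact fits with isolated outliers)
        delta = np.maximum(np.clip(1.0 - u**2, 0.0, 1.0) ** 2, 1e-12)
    return fitted


def lowess_smooth(positions, values, params: SmoothingParams | None = None) -> np.ndarray:
    """Smooth one track; thin wrapper over :func:`lowess_batch`."""
    params = params or SmoothingParams()
    out = lowess_batch(np.asarray(positions), np.asarray(values)[None, :], params)
    return out[0]
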