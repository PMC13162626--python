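"""Local polynomial (loess-style) scatterplot smoother.

Used to estimate the smooth SD-vs-mean trend of a normal expression bank.
Each local fit uses the nearest ``span`` fraction of the points, tricube
weighting, and a degree-1 or degree-2 polynomial.  For speed the fit is
evaluated on a grid spanning the predictor range and predictions at
arbitrary points are linearly interpolated; outside the observed range the
curve is clamped to its boundary value (no extrapolation).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["loess_fit"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    degree: int = 2,
    n_grid: int = 201,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit a loess curve of ``y`` on ``x`` and return a prediction callable.

    Parameters
    ----------
    x, y
        1-D arrays of equal length (at least ``degree + 2`` points).
    span
        Fraction of points in each local window, in (0, 1].
    degree
        Local polynomial degree, 1 or 2.
    n_grid
        Number of evaluation points; predictions elsewhere are interpolated.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if n < degree + 2:
        raise ValueError(f"loess needs at least {degree + 2} points, got {n}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")

    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # degenerate predictor: flat curve at the mean response
        c = float(y.mean())
        return lambda xq: np.full(np.shape(np.asarray(xq, float)), c)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    window = max(int(np.ceil(span * n)), degree + 2)
    grid = np.linspace(lo, hi, min(n_grid, n))
    fitted = np.empty_like(grid)
    starts = np.arange(n - window + 1)
    left, right = xs[starts], xs[starts + window - 1]
    for i, g in enumerate(grid):
        # contiguous window of `window` sorted points minimizing the bandwidth
        bw = np.maximum(g - left, right - g)
        best = int(np.argmin(bw))
        sl = slice(best, best + window)
        xw, yw = xs[sl], ys[sl]
        h = max(np.abs(xw - g).max(), 1e-300)
        w = _tricube((xw - g) / h)
        t = xw - g  # center for conditioning; intercept = fitted value at g
        cols = [np.ones_like(t), t] + ([t * t] if degree == 2 else [])
        X = np.stack(cols, axis=1)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
        fitted[i] = coef[0]

    def predict(xq: np.ndarray) -> np.ndarray:
        xq = np.asarray(xq, float)
        return np.interp(xq, grid, fitted)  # clamps to boundary values

    return predict
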