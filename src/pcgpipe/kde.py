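"""One-dimensional Gaussian kernel density estimation with mode finding.

The estimator is the classical Parzen window

    f_hat(x) = (1 / (n h)) * sum_i K((X_i - x) / h)

with the normalized Gaussian kernel K(u) = exp(-u^2 / 2) / sqrt(2*pi), so
the estimated density integrates to one.  Its grid argmax ("mode") is used
to find the most common recording duration of each class, which drives the
duration-based data selection rule.

Bandwidth "auto" is Silverman's rule of thumb,
h = 0.9 * min(sd, IQR / 1.34) * n^(-1/5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["KdeModel", "silverman_bandwidth", "kde_fit", "kde_eval", "kde_mode"]

logger = logging.getLogger(__name__)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class KdeModel:
    """Fitted 1-D KDE: the training points X_i and the window width h."""

    points: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).ravel()
        object.__setattr__(self, "points", pts)
        if pts.size == 0:
            raise ValueError("KDE requires at least one training point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("KDE training points must be finite")
        if not (self.bandwidth > 0 and np.isfinite(self.bandwidth)):
            raise ValueError(f"bandwidth must be positive and finite, got {self.bandwidth}")

    @property
    def n(self) -> int:
        return len(self.points)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb; falls back to 1.0 on zero-spread data."""
    x = np.asarray(values, dtype=np.float64).ravel()
    n = len(x)
    if n < 2:
        logger.warning("silverman bandwidth undefined for n<2; falling back to 1.0")
        return 1.0
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not candidates:
        logger.warning("zero-variance sample; falling back to bandwidth 1.0")
        return 1.0
    return 0.9 * min(candidates) * n ** (-0.2)


def kde_fit(values, bandwidth: float | str = "auto") -> KdeModel:
    """Fit a KDE to ``values`` with a fixed or Silverman ("auto") bandwidth."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot fit KDE to an empty sample")
    if isinstance(bandwidth, str):
        if bandwidth != "auto":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        h = silverman_bandwidth(x)
    else:
        h = float(bandwidth)
    return KdeModel(points=x, bandwidth=h)


def kde_eval(model: KdeModel, x) -> np.ndarray | float:
    """Evaluate the fitted density at scalar or array ``x``."""
    xq = np.asarray(x, dtype=np.float64)
    scalar = xq.ndim == 0
    q = np.atleast_1d(xq)
    h = model.bandwidth
    # (n_query, n_points) can be large for dense grids; chunk the queries
    out = np.empty(len(q))
    chunk = max(1, int(4_000_000 // max(1, model.n)))
    for start in range(0, len(q), chunk):
        u = (model.points[None, :] - q[start : start + chunk, None]) / h
        out[start : start + chunk] = np.exp(-0.5 * u * u).sum(axis=1) / (
            model.n * h * _SQRT_2PI
        )
    return float(out[0]) if scalar else out


def kde_mode(
    model: KdeModel, grid_min: float, grid_max: float, grid_step: float = 0.5
) -> float:
    """Grid point with the highest estimated density; ties go to the
    smallest grid value (``argmax`` returns the first maximum)."""
    if not grid_min < grid_max:
        raise ValueError("grid_min must be < grid_max")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    grid = np.arange(grid_min, grid_max + grid_step / 2, grid_step)
    density = kde_eval(model, grid)
    return float(grid[int(np.argmax(density))])
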