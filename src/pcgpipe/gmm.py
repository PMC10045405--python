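"""Gaussian mixture model fit by expectation-maximization, from scratch.

The mixture density is f(x | theta) = sum_k pi_k * N(x | mu_k, sigma_k^2)
with diagonal covariances.  EM alternates:

* E step: responsibilities t(i,k) = pi_k N(x_i|mu_k,sigma_k^2) /
  sum_j pi_j N(x_i|mu_j,sigma_j^2), computed in log space;
* M step: pi_k = mean_i t(i,k); mu_k = weighted mean; sigma_k^2 = weighted
  (biased) variance about the *updated* mean.

Used for "biclustering" data curation: fit M=2 components to the
(duration, SNR) statistics of a corpus and keep the denser cluster.
Variances are floored at 1e-6 to prevent singular collapse, and a
component whose total responsibility underflows is re-seeded from a random
data point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["GmmModel", "e_step", "m_step", "em_fit", "hard_assign", "log_likelihood"]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-6


@dataclass
class GmmModel:
    """Mixture parameters plus the per-iteration log-likelihood trace."""

    weights: np.ndarray  # (M,), sums to 1
    means: np.ndarray  # (M, d)
    variances: np.ndarray  # (M, d) diagonal covariances
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {self.weights.sum()}")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def _log_gaussian(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """log N(x_i | mu_k, diag sigma_k^2) for all (i, k) -> (n, M)."""
    diff = X[:, None, :] - means[None, :, :]  # (n, M, d)
    log_det = np.sum(np.log(2.0 * np.pi * variances), axis=1)  # (M,)
    quad = np.sum(diff * diff / variances[None, :, :], axis=2)  # (n, M)
    return -0.5 * (log_det[None, :] + quad)


def _log_joint(model: GmmModel, X: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(model.weights, 1e-300))[None, :] + _log_gaussian(
        X, model.means, model.variances
    )


def _as_matrix(data, n_features: int | None = None) -> np.ndarray:
    X = np.asarray(data, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"data dimension {X.shape[1]} does not match model {n_features}")
    return X


def log_likelihood(model: GmmModel, data) -> float:
    """Total log-likelihood of ``data`` under the mixture."""
    X = _as_matrix(data, model.n_features)
    return float(logsumexp(_log_joint(model, X), axis=1).sum())


def e_step(model: GmmModel, data) -> np.ndarray:
    """Responsibilities t(i,k), each row summing to 1 (log-space stable)."""
    X = _as_matrix(data, model.n_features)
    log_joint = _log_joint(model, X)
    log_norm = logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_joint - log_norm)


def m_step(
    data, resp: np.ndarray, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximization update: returns (weights, means, variances).

    A component with vanishing total responsibility is re-seeded at a random
    data point with the global variance (a logged recovery, not an error).
    """
    X = _as_matrix(data)
    resp = np.asarray(resp, dtype=np.float64)
    n, M = resp.shape
    if X.shape[0] != n:
        raise ValueError("responsibility rows must match data rows")
    totals = resp.sum(axis=0)  # N_k
    global_var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    weights = np.empty(M)
    means = np.empty((M, X.shape[1]))
    variances = np.empty((M, X.shape[1]))
    if rng is None:
        rng = np.random.default_rng(0)
    for k in range(M):
        if totals[k] < 1e-10:
            logger.warning("GMM component %d lost all responsibility; re-seeding", k)
            means[k] = X[rng.integers(len(X))]
            variances[k] = global_var
            weights[k] = 1.0 / n
            continue
        weights[k] = totals[k] / n
        means[k] = resp[:, k] @ X / totals[k]
        diff = X - means[k]
        variances[k] = np.maximum(resp[:, k] @ (diff * diff) / totals[k], VARIANCE_FLOOR)
    weights /= weights.sum()
    return weights, means, variances


def _init_means(X: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: spread initial means across the data."""
    n = len(X)
    chosen = [int(rng.integers(n))]
    for _ in range(1, M):
        d2 = np.min(
            ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total <= 0:
            chosen.append(int(rng.integers(n)))
            continue
        chosen.append(int(rng.choice(n, p=d2 / total)))
    return X[chosen].copy()


def em_fit(
    data,
    n_components: int = 2,
    seed: int = 42,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[GmmModel, np.ndarray]:
    """Fit an M-component diagonal GMM by EM; returns (model, responsibilities).

    Deterministic for a fixed seed.  The log-likelihood trace (one entry per
    E step) is non-decreasing up to floating-point slack — the defining
    property of EM.
    """
    X = _as_matrix(data)
    n, d = X.shape
    if n < n_components:
        raise ValueError(f"need at least {n_components} samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    rng = np.random.default_rng(seed)
    global_var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    model = GmmModel(
        weights=np.full(n_components, 1.0 / n_components),
        means=_init_means(X, n_components, rng),
        variances=np.tile(global_var, (n_components, 1)),
    )
    resp = e_step(model, X)
    prev_ll = -np.inf
    for _ in range(max_iter):
        ll = log_likelihood(model, X)
        model.log_likelihood_trace.append(ll)
        if abs(ll - prev_ll) < tol:
            model.converged = True
            break
        prev_ll = ll
        weights, means, variances = m_step(X, resp, rng)
        model.weights, model.means, model.variances = weights, means, variances
        resp = e_step(model, X)
    return model, resp


def hard_assign(resp: np.ndarray) -> np.ndarray:
    """Hard cluster labels: argmax responsibility per sample."""
    return np.argmax(resp, axis=1)
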