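"""Fuzzy c-means clustering core.

Standard FCM with Euclidean distances: memberships

    w_kl = 1 / sum_j (d_kl / d_kj)^(2/(m-1))

and centers as w^m-weighted means, iterated until the largest center
displacement falls below tolerance.  The fuzzifier m (> 1) controls how
soft the partition is; m = 2 is used throughout the package.  Fitting
restarts from several seeded random memberships and keeps the run with
the lowest objective sum_k sum_l w_kl^m d_kl^2.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = ["fit_fcm", "memberships", "fcm_objective"]

_ZERO_DIST = 1e-12


def memberships(centers: np.ndarray, X: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Membership weights of each row of ``X`` against frozen ``centers``.

    Rows sum to 1; a point coinciding with a center gets full membership
    there (split equally if it coincides with several).
    """
    X = np.asarray(X, dtype=float)
    centers = np.asarray(centers, dtype=float)
    d = cdist(X, centers)  # (K, c)
    W = np.zeros_like(d)
    zero = d < _ZERO_DIST
    has_zero = zero.any(axis=1)
    if has_zero.any():
        W[has_zero] = zero[has_zero] / zero[has_zero].sum(axis=1, keepdims=True)
    reg = np.where(~has_zero)[0]
    if reg.size:
        power = 2.0 / (m - 1.0)
        inv = d[reg] ** (-power)
        W[reg] = inv / inv.sum(axis=1, keepdims=True)
    return W


def fcm_objective(centers: np.ndarray, X: np.ndarray, W: np.ndarray, m: float = 2.0) -> float:
    """FCM objective J = sum_k sum_l w_kl^m * ||x_k - c_l||^2."""
    d2 = cdist(np.asarray(X, float), np.asarray(centers, float)) ** 2
    return float(np.sum(np.asarray(W, float) ** m * d2))


def _update_centers(X: np.ndarray, W: np.ndarray, m: float) -> np.ndarray:
    Wm = W ** m
    denom = Wm.sum(axis=0)[:, None]
    return (Wm.T @ X) / denom


def _single_fit(
    X: np.ndarray,
    c: int,
    m: float,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, float, int]:
    K = X.shape[0]
    W = rng.random((K, c))
    W /= W.sum(axis=1, keepdims=True)
    centers = _update_centers(X, W, m)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        W = memberships(centers, X, m)
        new_centers = _update_centers(X, W, m)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    W = memberships(centers, X, m)
    return centers, W, fcm_objective(centers, X, W, m), n_iter


def _centers_collapsed(centers: np.ndarray, tol: float = 1e-6) -> bool:
    d = cdist(centers, centers)
    np.fill_diagonal(d, np.inf)
    return bool(d.min() < tol)


def fit_fcm(
    X: np.ndarray,
    c: int = 6,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: Optional[int] = 0,
    n_restarts: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit fuzzy c-means on the rows of ``X``.

    Parameters
    ----------
    X : (K, E) array
        Standardized element space; K must exceed the cluster count.
    c : int
        Number of clusters (six: one per principal growth stage).
    m : float
        Fuzzifier, > 1.
    tol, max_iter
        Convergence tolerance on the maximum center displacement, and
        the iteration cap.
    seed : int
        Seeds the random membership initialisations.
    n_restarts : int
        Independent restarts; the solution with the lowest objective wins.

    Returns
    -------
    centers : (c, E) array
    W : (K, c) partition matrix, rows summing to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D element space")
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    if X.shape[0] <= c:
        raise ValueError(f"need more than c={c} elements, got {X.shape[0]}")

    rng = np.random.default_rng(seed)
    best = None
    attempts = 0
    done = 0
    while done < n_restarts:
        attempts += 1
        if attempts > 4 * n_restarts:
            raise RuntimeError("fuzzy c-means repeatedly collapsed duplicate centers")
        centers, W, obj, n_iter = _single_fit(X, c, m, tol, max_iter, rng)
        if _centers_collapsed(centers):
            logger.warning("degenerate FCM solution (coincident centers); re-initialising")
            continue
        done += 1
        if best is None or obj < best[2]:
            best = (centers, W, obj, n_iter)
    centers, W, obj, n_iter = best
    logger.debug("fcm converged: objective=%.6g iterations=%d", obj, n_iter)
    return centers, W
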