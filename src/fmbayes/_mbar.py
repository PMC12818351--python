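"""Multistate Bennett acceptance ratio (MBAR) free-energy estimator.

Implements the standard self-consistent estimator for dimensionless free
energies of K thermodynamic states from samples drawn at each state, with
the asymptotic covariance of the estimates, plus the integrated
autocorrelation ("statistical inefficiency") used to thin correlated chains
before estimation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["mbar", "overlap_matrix", "statistical_inefficiency", "subsample"]


def mbar(u_kn: np.ndarray, N_k, tol: float = 1e-8, max_iter: int = 10_000):
    """Estimate dimensionless free energies f_k and their covariance.

    Parameters
    ----------
    u_kn : (K, N_tot) array
        Reduced energy of every pooled sample n evaluated in every state k.
    N_k : (K,) array of int
        Number of samples contributed by each state (sum = N_tot).

    Returns
    -------
    f_k : (K,) array with f_0 = 0.
    theta : (K, K) covariance matrix of the f_k estimates; the uncertainty
        of a difference f_j - f_i is sqrt(theta_ii + theta_jj - 2 theta_ij).

    Raises
    ------
    RuntimeError if self-consistent iteration does not converge; the message
    names the pair of neighboring states with the least overlap.
    """
    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=float)
    K, N_tot = u_kn.shape
    if N_k.shape != (K,) or N_k.sum() != N_tot:
        raise ValueError("N_k must sum to the pooled sample count")
    if np.any(N_k <= 0):
        raise ValueError("every state must contribute at least one sample")

    # work with energies shifted per-sample to avoid overflow
    shift = u_kn.min(axis=0)
    u = u_kn - shift[None, :]

    f_k = np.zeros(K)
    log_N = np.log(N_k)
    for _ in range(max_iter):
        # log denominator per sample: ln sum_k N_k exp(f_k - u_k(x_n))
        log_den = logsumexp(f_k[:, None] - u + log_N[:, None], axis=0)
        f_new = -logsumexp(-u - log_den[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f_k))
        f_k = f_new
        if delta < tol:
            break
    else:
        ov = overlap_matrix(u_kn, N_k, f_k)
        worst = int(np.argmin([ov[i, i + 1] for i in range(K - 1)]))
        raise RuntimeError(
            "MBAR self-consistency did not converge; worst neighbor overlap "
            f"between states {worst} and {worst + 1} "
            f"({ov[worst, worst + 1]:.2e})")

    theta = _covariance(u, f_k, N_k)
    return f_k, theta


def _weights(u, f_k, N_k):
    """Normalized MBAR weight matrix W (N_tot, K): column sums are 1."""
    log_den = logsumexp(f_k[:, None] - u + np.log(N_k)[:, None], axis=0)
    log_w = f_k[:, None] - u - log_den[None, :]
    return np.exp(log_w).T


def _covariance(u, f_k, N_k):
    """Asymptotic covariance of f_k via the SVD form of the estimator."""
    W = _weights(u, f_k, N_k)           # (N_tot, K)
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    Sm = np.diag(S)
    inner = np.eye(len(S)) - Sm @ Vt @ np.diag(N_k) @ Vt.T @ Sm
    theta = Vt.T @ Sm @ np.linalg.pinv(inner, rcond=1e-10) @ Sm @ Vt
    return theta


def overlap_matrix(u_kn, N_k, f_k=None):
    """Matrix O_ij estimating phase-space overlap between states i and j.

    O = N_k-weighted W^T W; rows sum to 1.  Small off-diagonal neighbor
    entries flag poor bridge sampling.
    """
    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=float)
    if f_k is None:
        f_k, _ = mbar(u_kn, N_k)
    u = u_kn - u_kn.min(axis=0)[None, :]
    W = _weights(u, f_k, N_k)
    return W.T @ (W * N_k[None, :])


def statistical_inefficiency(x, mintime: int = 3) -> float:
    """Integrated autocorrelation factor g = 1 + 2 tau of a scalar series.

    Uses the standard initial-positive-sequence truncation: accumulate
    normalized autocorrelations until they first go negative (after
    ``mintime`` lags).  g = 1 for white noise; thinning a chain by g yields
    approximately independent samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return 1.0
    dx = x - x.mean()
    var = dx @ dx / n
    if var == 0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = dx[:-t] @ dx[t:] / ((n - t) * var)
        if c <= 0 and t > mintime:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


def subsample(x, g=None):
    """Indices of an (approximately) decorrelated subsample of a series."""
    x = np.asarray(x, dtype=float)
    if g is None:
        g = statistical_inefficiency(x)
    stride = max(1, int(np.ceil(g)))
    return np.arange(0, x.size, stride)
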