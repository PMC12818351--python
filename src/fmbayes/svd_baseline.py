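"""Regularized-SVD fit of Karplus coefficients — the classical baseline.

Given known dihedral angles and state populations, the coefficients solve a
linear least-squares problem: each observable contributes one row
``(<cos^2(phi+phi0)>, <cos(phi+phi0)>, 1)`` of population-weighted basis
averages, and theta = V (Sigma + eps I)^-1 U^T J_exp with a small
regularization eps on the singular values.  Uncertainty comes from repeated
refits with a random fraction of observables held out (delete-d jackknife).
"""

from __future__ import annotations

import warnings

import numpy as np

from .forward_models import DihedralEnsemble

__all__ = ["build_design_matrix", "svd_fit", "jackknife_uncertainty"]


def build_design_matrix(ensemble: DihedralEnsemble, populations=None,
                        phi0: float = 0.0) -> np.ndarray:
    """Population-weighted (N_d x 3) Karplus design matrix.

    ``populations`` may be a per-state vector p(X) or a (n_states, n_obs)
    matrix of per-observable state weights; defaults to the ensemble's prior
    populations.  Each weighting must sum to 1 over states.
    """
    pop = ensemble.prior_pop if populations is None else np.asarray(populations, dtype=float)
    if pop.ndim == 1:
        if pop.size != ensemble.n_states:
            raise ValueError("populations length must equal n_states")
        pop = np.broadcast_to(pop[:, None], ensemble.phi.shape)
    elif pop.shape != ensemble.phi.shape:
        raise ValueError("population matrix must be (n_states, n_obs)")
    if np.any(np.abs(pop.sum(axis=0) - 1.0) > 1e-8):
        raise ValueError("populations must sum to 1 over states")
    c = np.cos(np.deg2rad(ensemble.phi + phi0))
    col1 = np.einsum("xj,xj->j", pop, c * c)
    col2 = np.einsum("xj,xj->j", pop, c)
    return np.column_stack([col1, col2, np.ones(ensemble.n_obs)])


def svd_fit(M: np.ndarray, J_exp, eps: float = 1e-6) -> np.ndarray:
    """Solve for (A, B, C) by the eps-regularized pseudo-inverse.

    eps is added to every singular value, which bounds the inverse and keeps
    near-degenerate basis directions from exploding; for well-conditioned
    designs the perturbation is of order eps relative to the exact solution.
    """
    M = np.asarray(M, dtype=float)
    J = np.asarray(J_exp, dtype=float)
    if M.ndim != 2 or M.shape[1] != 3:
        raise ValueError("design matrix must be (N_d, 3)")
    if M.shape[0] < 3:
        raise ValueError("need at least 3 observables to fit 3 coefficients")
    if J.shape != (M.shape[0],):
        raise ValueError("J_exp length must match the design matrix rows")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s[-1] < 1e3 * eps:
        warnings.warn(
            f"design matrix nearly rank-deficient (condition number {s[0] / max(s[-1], 1e-300):.3g}); "
            "coefficients are regularization-limited",
            stacklevel=2,
        )
    return Vt.T @ ((U.T @ J) / (s + eps))


def jackknife_uncertainty(M: np.ndarray, J_exp, n_iter: int = 1000,
                          holdout_frac: float = 0.1, seed=None) -> np.ndarray:
    """Per-coefficient SD over n_iter refits, each omitting a random holdout.

    The number of omitted rows is floor(holdout_frac * N_d), at least 1; the
    remaining rows must still determine the 3 coefficients.
    """
    M = np.asarray(M, dtype=float)
    J = np.asarray(J_exp, dtype=float)
    n = M.shape[0]
    n_out = max(1, int(np.floor(holdout_frac * n)))
    if n - n_out < 3:
        raise ValueError("holdout leaves fewer than 3 observables")
    rng = np.random.default_rng(seed)
    thetas = np.empty((n_iter, 3))
    for i in range(n_iter):
        keep = np.ones(n, dtype=bool)
        keep[rng.choice(n, size=n_out, replace=False)] = False
        thetas[i] = svd_fit(M[keep], J[keep])
    return thetas.std(axis=0, ddof=1)
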