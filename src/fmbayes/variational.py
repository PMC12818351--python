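"""Variational optimization of forward-model parameters by score minimization.

Instead of sampling theta in the posterior, the evidence score f(theta) is
minimized directly with L-BFGS-B, using the Boltzmann-averaged energy
gradient as df/dtheta.  Each objective evaluation launches a fresh (short)
stochastic estimate of the score; within one optimization start the same
random seed is reused for every evaluation (common random numbers), which
makes the objective a deterministic function of theta and keeps quasi-Newton
line searches coherent.  Independent starts use different seeds, and their
dispersion doubles as an uncertainty estimate when the score landscape is
not convex enough for Hessian inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .forward_models import DihedralEnsemble, KarplusModel
from .sampler import SamplerConfig
from .score import XiSchedule, compute_score, sample_xi_states, score_from_traces, score_gradient

__all__ = ["OptimizationResult", "minimize_score", "multistart_uncertainty"]


@dataclass
class OptimizationResult:
    """Best minimum over starts plus per-start detail."""

    theta_star: np.ndarray
    f_star: float
    grad_norm: float
    per_start_theta: np.ndarray     # (n_starts, 3)
    per_start_f: np.ndarray
    uncertainty: np.ndarray | None  # per-parameter SD across starts
    n_evaluations: int


def _make_objective(config: SamplerConfig, ensemble, data, phi0, label,
                    schedule: XiSchedule, counter: list):
    """Return f(theta), grad(theta) with common random numbers per start."""

    def objective(theta):
        counter[0] += 1
        model = KarplusModel(*theta, phi0=phi0, label=label)
        traces = sample_xi_states(config, ensemble, data, model, schedule)
        res = score_from_traces(traces, schedule, config.n_replicas)
        grad, _ = score_gradient(traces[-1])
        return res.f, grad.ravel()

    return objective


def minimize_score(init_thetas, config: SamplerConfig,
                   ensemble: DihedralEnsemble, data,
                   phi0: float = 0.0, label: str = "3J",
                   schedule: XiSchedule | None = None,
                   bounds=None, gtol: float = 1e-3,
                   maxiter: int = 50) -> OptimizationResult:
    """L-BFGS-B minimization of the score from one or more starts.

    Parameters
    ----------
    init_thetas : sequence of (A, B, C) starting points.
    config : sampler settings for each stochastic score evaluation;
        ``config.n_replicas`` defaults matter (variational runs typically
        use few replicas for speed) and ``config.n_steps`` is the MC budget
        per xi state per evaluation.
    bounds : box for (A, B, C); defaults to (-15, 15) Hz per coefficient.
    """
    init_thetas = np.atleast_2d(np.asarray(init_thetas, dtype=float))
    if init_thetas.shape[1] != 3:
        raise ValueError("each start must be a 3-vector (A, B, C)")
    if schedule is None:
        schedule = XiSchedule.power(6)
    if bounds is None:
        bounds = [(config.theta_lo, config.theta_hi)] * 3

    per_theta, per_f, n_eval = [], [], 0
    failures = []
    for s, theta0 in enumerate(init_thetas):
        counter = [0]
        cfg = replace(config, seed=config.seed + 104729 * s)
        obj = _make_objective(cfg, ensemble, data, phi0, label, schedule,
                              counter)
        res = minimize(obj, theta0, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": maxiter, "gtol": gtol,
                                "ftol": 1e-8})
        n_eval += counter[0]
        if not np.all(np.isfinite(res.x)):
            failures.append((s, res.message))
            continue
        per_theta.append(res.x)
        per_f.append(res.fun)
    if not per_theta:
        raise RuntimeError(f"every optimization start failed: {failures}")

    per_theta = np.asarray(per_theta)
    per_f = np.asarray(per_f)
    best = int(np.argmin(per_f))
    theta_star = per_theta[best]

    # gradient norm at the reported optimum, re-estimated with the best seed
    cfg = replace(config, seed=config.seed + 104729 * best)
    obj = _make_objective(cfg, ensemble, data, phi0, label, schedule, [0])
    _, g = obj(theta_star)
    unc = multistart_uncertainty(per_theta) if len(per_theta) >= 2 else None
    return OptimizationResult(theta_star=theta_star, f_star=float(per_f[best]),
                              grad_norm=float(np.linalg.norm(g)),
                              per_start_theta=per_theta, per_start_f=per_f,
                              uncertainty=unc, n_evaluations=n_eval)


def multistart_uncertainty(per_start_theta) -> np.ndarray:
    """Component-wise sample SD of converged parameters across starts."""
    t = np.atleast_2d(np.asarray(per_start_theta, dtype=float))
    if t.shape[0] < 2:
        raise ValueError("need at least two completed starts")
    return t.std(axis=0, ddof=1)
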