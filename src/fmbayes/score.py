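"""Evidence score: the free energy of switching on experimental restraints.

A forward model with parameters theta is scored by f(theta) = -ln Z(theta)/Z0,
the negative log Bayes factor between the restrained posterior ensemble and
an unrestrained reference.  The bridge is a family of distributions whose
data likelihood is raised to an exponent xi in [0, 1] (xi = 0: prior only;
xi = 1: full restraints), sampled at several intermediate xi values and
combined with the MBAR estimator.  Lower scores mean stronger total evidence
for the model; because the restraint energy grows linearly with the replica
count N_r, the reduced score f / N_r is reported alongside.

The gradient of the score with respect to the forward-model parameters is
the Boltzmann average of the energy gradient over the fully restrained
(xi = 1) ensemble, which makes the score directly usable as a variational
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _mbar
from .forward_models import DihedralEnsemble, KarplusModel
from .sampler import PosteriorTrace, SamplerConfig, run_chain

__all__ = [
    "XiSchedule",
    "FreeEnergyResult",
    "restraint_energy_at_xi",
    "sample_xi_states",
    "compute_score",
    "score_from_traces",
    "score_gradient",
    "optimize_xi_schedule",
    "hessian_uncertainty",
]


@dataclass(frozen=True)
class XiSchedule:
    """Ordered restraint-strength values in [0, 1] including both endpoints."""

    xi_values: tuple = tuple(np.linspace(0.0, 1.0, 11))

    def __post_init__(self):
        v = np.asarray(self.xi_values, dtype=float)
        if v.size < 2 or v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule must run from 0 to 1")
        if np.any(np.diff(v) <= 0):
            raise ValueError("schedule must be strictly increasing")
        object.__setattr__(self, "xi_values", tuple(float(x) for x in v))

    @classmethod
    def uniform(cls, count: int = 11) -> "XiSchedule":
        if count < 2:
            raise ValueError("need at least the two endpoint states")
        return cls(tuple(np.linspace(0.0, 1.0, count)))

    @classmethod
    def power(cls, count: int = 11, exponent: float = 2.0) -> "XiSchedule":
        """Nodes concentrated near xi = 0, where switching on the restraint
        changes the ensemble fastest (the thermodynamic length is largest)."""
        if count < 2:
            raise ValueError("need at least the two endpoint states")
        return cls(tuple(np.linspace(0.0, 1.0, count) ** exponent))

    def __len__(self):
        return len(self.xi_values)


@dataclass
class FreeEnergyResult:
    """Restraint free energy f (nats) with uncertainty and provenance."""

    f: float
    df: float
    f_reduced: float
    xi_values: np.ndarray
    per_state_f: np.ndarray
    n_samples_per_state: np.ndarray

    def to_dict(self) -> dict:
        return {
            "f": self.f,
            "df": self.df,
            "f_reduced": self.f_reduced,
            "xi_values": list(map(float, self.xi_values)),
            "per_state_free_energies": list(map(float, self.per_state_f)),
            "n_samples_per_state": list(map(int, self.n_samples_per_state)),
        }


def restraint_energy_at_xi(xi: float, prior_energy: float,
                           data_energy: float) -> float:
    """u_xi = prior terms + xi * (data-likelihood terms).

    At xi = 0 the energy is independent of the experimental data; at xi = 1
    it is the full posterior energy.  Affine in xi by construction.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return float(prior_energy) + xi * float(data_energy)


def sample_xi_states(config: SamplerConfig, ensemble: DihedralEnsemble, data,
                     models, schedule: XiSchedule) -> list:
    """Run one chain per xi state with theta pinned; returns the traces.

    The score is the evidence of a FIXED forward-model parameterization:
    the posterior is conditioned on theta, so only conformational states
    and uncertainty nuisance parameters fluctuate along the bridge.
    """
    traces = []
    for i, xi in enumerate(schedule.xi_values):
        cfg = replace(config, xi=float(xi), seed=config.seed + 7919 * i,
                      record_states=False, lrate=0.0, eta=0.0,
                      step_theta=0.0)
        traces.append(run_chain(cfg, ensemble, data, models))
    return traces


def score_from_traces(traces: list, schedule: XiSchedule,
                      n_replicas: int, thin: bool = True) -> FreeEnergyResult:
    """MBAR free-energy difference f(xi: 0 -> 1) from per-state traces.

    Samples are thinned by the integrated autocorrelation of their own
    u_xi series before pooling (MBAR assumes independent samples); the
    affine form of u_xi lets every sample be re-evaluated in every state
    from its recorded prior and data parts.
    """
    xis = np.asarray(schedule.xi_values)
    upr, uda, n_k = [], [], []
    for tr in traces:
        idx = _mbar.subsample(tr.u) if thin else np.arange(len(tr))
        upr.append(tr.u_prior[idx])
        uda.append(tr.u_data[idx])
        n_k.append(idx.size)
    upr = np.concatenate(upr)
    uda = np.concatenate(uda)
    # a sample whose data term is infinite (nuisance state below the gate
    # floor, reachable only where xi = 0) has zero weight in every xi > 0
    # state; at xi = 0 its data contribution is exactly zero
    with np.errstate(invalid="ignore"):
        u_kn = upr[None, :] + np.where(xis[:, None] > 0,
                                       xis[:, None] * uda[None, :], 0.0)
    f_k, theta = _mbar.mbar(u_kn, n_k)
    df = float(np.sqrt(max(0.0, theta[0, 0] + theta[-1, -1]
                           - 2.0 * theta[0, -1])))
    f = float(f_k[-1] - f_k[0])
    return FreeEnergyResult(f=f, df=df, f_reduced=f / n_replicas,
                            xi_values=xis, per_state_f=f_k,
                            n_samples_per_state=np.asarray(n_k))


def compute_score(config: SamplerConfig, ensemble: DihedralEnsemble, data,
                  models, schedule: XiSchedule | None = None) -> FreeEnergyResult:
    """Score a forward model: sample the xi bridge and estimate f by MBAR."""
    if schedule is None:
        schedule = XiSchedule()
    traces = sample_xi_states(config, ensemble, data, models, schedule)
    return score_from_traces(traces, schedule, config.n_replicas)


def score_gradient(trace_at_one: PosteriorTrace, thin: bool = True):
    """df/dtheta = <du/dtheta> over the fully restrained ensemble.

    Returns (gradient (K, 3), standard error of the mean per component).
    """
    if len(trace_at_one) == 0:
        raise ValueError("empty sample set")
    grads = trace_at_one.grads
    if thin:
        idx = _mbar.subsample(trace_at_one.u)
        grads = grads[idx]
    mean = grads.mean(axis=0)
    sem = grads.std(axis=0) / np.sqrt(grads.shape[0])
    return mean, sem


def optimize_xi_schedule(pilot_traces: list, pilot_schedule: XiSchedule,
                         target_count: int = 11) -> XiSchedule:
    """Space xi states equidistantly in (approximate) thermodynamic length.

    The local metric is the standard deviation of the xi-coupled (data)
    energy at each pilot state: dL = std[u_data](xi) dxi.  The cumulative
    length is integrated by trapezoid over the pilot grid and inverted for
    equal-arc-length nodes, keeping the endpoints pinned at 0 and 1.
    """
    xis = np.asarray(pilot_schedule.xi_values)
    sds = []
    for tr in pilot_traces:
        finite = tr.u_data[np.isfinite(tr.u_data)]
        sds.append(float(np.std(finite)) if finite.size > 1 else 0.0)
    sds = np.asarray(sds)
    if len(sds) != len(xis):
        raise ValueError("one pilot trace per pilot xi value required")
    if np.all(sds == 0):
        warnings.warn("degenerate pilot (zero energy variance); "
                      "returning a uniform schedule", stacklevel=2)
        return XiSchedule.uniform(target_count)
    # cumulative thermodynamic length by trapezoid
    seg = 0.5 * (sds[1:] + sds[:-1]) * np.diff(xis)
    L = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, L[-1], target_count)
    nodes = np.interp(targets, L, xis)
    nodes[0], nodes[-1] = 0.0, 1.0
    # enforce strict monotonicity against flat metric stretches
    for i in range(1, target_count):
        if nodes[i] <= nodes[i - 1]:
            nodes[i] = nodes[i - 1] + 1e-6
    nodes = np.clip(nodes, 0.0, 1.0)
    nodes[-1] = 1.0
    return XiSchedule(tuple(nodes))


def hessian_uncertainty(theta_star, grad_function, step: float = 0.05):
    """Parameter covariance from the inverted Hessian of the score.

    The Hessian is built from central finite differences of the score
    gradient around the optimum (the forward model itself contributes no
    second-derivative terms for a linear-in-parameters relation).  The
    covariance of the optimal parameters is its inverse; a non-positive-
    definite Hessian raises, advising multi-start variance instead.
    """
    theta_star = np.asarray(theta_star, dtype=float)
    m = theta_star.size
    H = np.empty((m, m))
    for i in range(m):
        e = np.zeros(m)
        e[i] = step
        gp = np.asarray(grad_function(theta_star + e), dtype=float)
        gm = np.asarray(grad_function(theta_star - e), dtype=float)
        H[:, i] = (gp - gm) / (2.0 * step)
    H = 0.5 * (H + H.T)
    vals = np.linalg.eigvalsh(H)
    if np.any(vals <= 0):
        raise np.linalg.LinAlgError(
            "score Hessian is not positive definite (eigenvalues "
            f"{vals}); the landscape is locally non-convex — use the "
            "variance across multi-start optimizations instead")
    return np.linalg.inv(H)
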