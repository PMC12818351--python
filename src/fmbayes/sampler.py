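"""Posterior sampling of replica states, nuisance parameters and FM parameters.

The posterior couples three groups of unknowns: which conformational states
the N replicas occupy, the uncertainty nuisance parameters (sigma_B and the
variance inflator phi per observable type), and the forward-model
coefficients theta.  A composite Metropolis–Hastings sweep updates each group
in turn; theta proposals are gradient-informed during burn-in
(theta_trial = theta - l_rate * grad_u + eta * z) and revert to a plain
symmetric random walk afterwards, which keeps the production kernel exactly
reversible without a Hastings correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .forward_models import DihedralEnsemble, KarplusModel
from .likelihoods import PriorBounds, SeveritySpec

__all__ = [
    "SamplerConfig",
    "PosteriorTrace",
    "propose_fm_params",
    "mh_accept",
    "run_chain",
    "gelman_rubin",
    "marginal_summary",
]

_LIK_CODES = {"gaussian": 0, "good_bad": 1, "good_bad_multi": 2}


@dataclass
class SamplerConfig:
    """Settings of one MCMC chain.

    Defaults mirror the synthetic-study protocol: 32 replicas, 10k burn-in
    sweeps with gradient-informed theta proposals, 50k production sweeps of
    pure random-walk sampling.
    """

    n_replicas: int = 32
    n_burn: int = 10_000
    n_steps: int = 50_000
    lrate: float = 1e-4       # burn-in gradient step on theta
    eta: float = 0.01         # burn-in proposal noise on theta (Hz)
    step_theta: float = 0.02  # production random-walk width on theta (Hz)
    step_sigma: float = 0.1   # log-space walk width on sigma_B
    step_phi: float = 0.1     # log-space walk width on phi
    gibbs_every: int = 4      # heat-bath replica draw every this many sweeps
    nuisance_gibbs_every: int = 25   # grid heat-bath draw of sigma/phi cadence
    seed: int = 0
    n_chains: int = 1
    likelihood: str = "good_bad"
    xi: float = 1.0           # restraint strength exponent on the data term
    bounds: PriorBounds = field(default_factory=PriorBounds)
    theta_lo: float = -15.0
    theta_hi: float = 15.0
    severity: SeveritySpec | None = None   # only for good_bad_multi
    ensemble_average: str = "replica"      # "replica" | "population"
    anneal_burn: bool = True               # ramp the restraint over burn-in
    wls_jumps: bool = True                 # Hastings-corrected basin hopping
    sem_in_width: bool = True              # fold SEM into the likelihood width
    counting: str = "restraint"            # replica counting in the data term
    record_states: bool = True

    def __post_init__(self):
        if min(self.n_replicas, self.n_burn + 1, self.n_steps) < 1:
            raise ValueError("counts must be positive")
        if self.lrate < 0 or self.eta < 0:
            raise ValueError("lrate and eta must be nonnegative")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if self.likelihood not in _LIK_CODES:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.likelihood == "good_bad_multi" and self.severity is None:
            raise ValueError("good_bad_multi requires a SeveritySpec")
        if self.ensemble_average not in ("replica", "population"):
            raise ValueError(
                f"unknown ensemble_average {self.ensemble_average!r}")
        if self.counting not in ("evidence", "restraint"):
            raise ValueError(f"unknown counting {self.counting!r}")


@dataclass
class PosteriorTrace:
    """Production-phase record of one chain."""

    thetas: np.ndarray        # (n_steps, K, 3)
    sigmas: np.ndarray        # (n_steps, K)
    phis: np.ndarray          # (n_steps, K, M)
    u: np.ndarray             # (n_steps,) total energy at the chain's xi
    u_prior: np.ndarray       # (n_steps,) replica-prior part
    u_data: np.ndarray        # (n_steps,) full-strength data part
    grads: np.ndarray         # (n_steps, K, 3) du/dtheta at each step
    states: np.ndarray        # (n_steps, N) or empty if not recorded
    acceptance: dict          # move class -> (attempts, accepted)
    type_labels: list
    config: SamplerConfig

    def __len__(self):
        return self.u.shape[0]

    def acceptance_rates(self) -> dict:
        return {k: (a[1] / a[0] if a[0] else np.nan)
                for k, a in self.acceptance.items()}


def propose_fm_params(theta_old, gradient, lrate, eta, rng) -> np.ndarray:
    """Gradient-informed proposal theta - l_rate * grad + eta * z."""
    theta_old = np.asarray(theta_old, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    return theta_old - lrate * gradient + eta * rng.standard_normal(theta_old.shape)


def mh_accept(u_new: float, u_old: float, rng) -> bool:
    """Metropolis acceptance with probability min(1, exp(-(u_new - u_old)))."""
    if np.isnan(u_new) or np.isnan(u_old):
        return False
    du = u_new - u_old
    if du <= 0:
        return True
    return bool(rng.random() < np.exp(-du))


def _prepare(ensemble: DihedralEnsemble, data, models: dict):
    labels = ensemble.type_labels
    for lbl in labels:
        if lbl not in models:
            raise ValueError(f"no model supplied for observable type {lbl!r}")
    type_idx = np.empty(ensemble.n_obs, dtype=np.int64)
    phase = np.empty(ensemble.n_obs)
    for k, lbl in enumerate(labels):
        mask = ensemble.obs_type == lbl
        type_idx[mask] = k
        phase[mask] = models[lbl].phi0
    cosx = np.cos(np.deg2rad(ensemble.phi + phase[None, :]))
    d = np.asarray(data, dtype=float)
    if d.shape != (ensemble.n_obs,):
        raise ValueError("data length must equal the observable count")
    if not np.all(np.isfinite(d)):
        raise ValueError("experimental data must be finite")
    return labels, type_idx, cosx, d


def run_chain(config: SamplerConfig, ensemble: DihedralEnsemble, data,
              models: dict | KarplusModel, init_sigma: float = 1.0,
              init_phi: float = 1.5) -> PosteriorTrace:
    """Sample the joint posterior; returns the production trace.

    Parameters
    ----------
    models : mapping label -> KarplusModel (or a single model for
        single-type ensembles); supplies per-type phase offsets and the
        initial theta of each type.
    init_sigma, init_phi : initial nuisance values (every type).
    """
    if isinstance(models, KarplusModel):
        models = {lbl: models for lbl in ensemble.type_labels}
    labels, type_idx, cosx, d = _prepare(ensemble, data, models)
    K = len(labels)
    lik = _LIK_CODES[config.likelihood]
    if lik == 2:
        phi_levels = config.severity.phi_levels
    elif lik == 1:
        phi_levels = np.array([1.0, float(init_phi)])
    else:
        phi_levels = np.array([1.0])
    M = phi_levels.size
    b = config.bounds
    init_sigma = float(np.clip(init_sigma, b.sigma_lo, b.sigma_hi))

    theta0 = np.array([models[lbl].theta for lbl in labels])
    sigma0 = np.full(K, init_sigma)
    phi0 = np.tile(phi_levels, (K, 1))

    rng = np.random.default_rng(config.seed)
    states0 = rng.integers(0, ensemble.n_states,
                           size=config.n_replicas).astype(np.int64)
    kern_seed = int(rng.integers(0, 2**31 - 1))

    with np.errstate(over="ignore"):
        (theta_tr, sigma_tr, phi_tr, u_tr, upr, uda, grad_tr, states_tr,
         acc) = _kernel.run_chain_kernel(
            cosx, cosx * cosx, np.log(ensemble.prior_pop), d, type_idx, K,
            lik, M, config.n_replicas,
            1 if config.counting == "restraint" else 0, config.xi,
            config.ensemble_average == "population", ensemble.prior_pop,
            theta0, sigma0, phi0, states0,
            config.n_burn, config.n_steps, config.gibbs_every,
            config.nuisance_gibbs_every,
            np.geomspace(b.sigma_lo, b.sigma_hi, 128),
            np.geomspace(b.phi_lo if b.phi_lo > 0 else 1.0, b.phi_hi, 128),
            config.lrate, config.eta, config.step_theta,
            config.step_sigma, config.step_phi,
            b.sigma_lo, b.sigma_hi, b.phi_hi,
            config.theta_lo, config.theta_hi,
            config.anneal_burn, config.wls_jumps, config.sem_in_width,
            kern_seed, config.record_states)

    if not np.all(np.isfinite(u_tr)):
        raise FloatingPointError(
            "non-finite chain energy; check data scale, initial parameters "
            f"and prior bounds (first bad step {int(np.argmax(~np.isfinite(u_tr)))})")
    names = ["replica", "sigma", "phi", "theta"]
    return PosteriorTrace(
        thetas=theta_tr, sigmas=sigma_tr, phis=phi_tr, u=u_tr,
        u_prior=upr, u_data=uda, grads=grad_tr, states=states_tr,
        acceptance={n: tuple(acc[i]) for i, n in enumerate(names)},
        type_labels=list(labels), config=config)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat from >= 2 equal-length chains.

    ``chains`` is (n_chains, n_samples) for one scalar parameter.  Computed
    from the classic between/within-chain variance decomposition.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = x.shape
    within = x.var(axis=1, ddof=1).mean()
    if within == 0:
        raise ValueError("zero within-chain variance")
    between = n * x.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def marginal_summary(trace: PosteriorTrace | list) -> dict:
    """Pooled mean, SD and histogram-MAP per FM coefficient and type.

    Accepts one trace or a list of traces (pooled production samples).  MAP
    uses a Freedman–Diaconis histogram with a floor of 30 bins.
    """
    traces = trace if isinstance(trace, (list, tuple)) else [trace]
    if not traces or any(len(t) == 0 for t in traces):
        raise ValueError("empty trace")
    thetas = np.concatenate([t.thetas for t in traces], axis=0)
    labels = traces[0].type_labels
    out = {}
    for k, lbl in enumerate(labels):
        out[lbl] = {}
        for i, name in enumerate(("A", "B", "C")):
            s = thetas[:, k, i]
            out[lbl][name] = {
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0,
                "map": _hist_map(s),
            }
    return out


def _hist_map(samples: np.ndarray) -> float:
    s = np.asarray(samples, dtype=float)
    if s.max() == s.min():
        return float(s[0])
    iqr = np.subtract(*np.percentile(s, [75, 25]))
    if iqr > 0:
        width = 2 * iqr / s.size ** (1 / 3)
        n_bins = int(np.ceil((s.max() - s.min()) / width))
    else:
        n_bins = 30
    n_bins = max(n_bins, 30)
    hist, edges = np.histogram(s, bins=n_bins)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))
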