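"""Energy functions u = -ln(posterior) for ensemble-averaged couplings.

Three likelihood models are provided, all built from the same Gaussian
scale-mixture machinery:

* ``gaussian`` — a single Gaussian of width sigma0 per observable type.
* ``good_bad`` — a two-component mixture in which "good" observables carry
  variance ``sigma0^2`` and "bad" (outlier) observables carry the inflated
  variance ``phi^2 sigma0^2``; the unknown bad fraction omega is marginalized
  analytically under a uniform prior, leaving half-weight components with an
  extra ``1/phi`` factor on the wide one.  At ``phi = 1`` it reduces exactly
  to the Gaussian model.
* ``good_bad_multi`` — the M-level severity generalization with inflators
  ``phi_1 = 1 < phi_2 < ... < phi_M`` and Dirichlet-marginalized equal
  weights ``1/M``.

Each observable carries the total uncertainty
``sigma0_j = sqrt(sigma_B^2 + sigma_SEM_j^2)``, combining the sampled
Bayesian uncertainty with the finite-sampling error of the replica average.
Heaviside gates from the marginalization keep mixture component m for
observable j only while ``phi_m * sigma0_j >= sigma_SEM_j`` (convention
H(x) = 1 for x > 0, H(0) = 0); with the quadrature form of sigma0 the gates
are open by construction and only guard pathological float cases.

Replica counting (``counting=``): how the replica count N enters the data
term.  ``"evidence"`` multiplies each observable's full log-mixture by N —
the energy exactly as the replica-averaged posterior is usually written.
``"restraint"`` replicates the Gaussian components instead,
``sum_m w_m N(d | g, phi_m^2 sigma0_j^2)^N``: the maximum-entropy restraint
is applied N times while the good-vs-bad class of a datum — a single latent
property of the datum, not of each replica — is counted once.  The two
coincide for the single-component Gaussian model up to N-1 copies of the
normalizer, and both reduce to the same expression at N = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_models import PredictionSet

__all__ = [
    "UncertaintyState",
    "SeveritySpec",
    "PriorBounds",
    "gaussian_energy",
    "goodbad_energy",
    "goodbad_grad_theta",
    "multiseverity_energy",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorBounds:
    """Truncated Jeffreys priors: uniform densities in ln(sigma_B), ln(phi).

    Improper 1/x priors are truncated to a bounded support so that the
    posterior (and the evidence behind the restraint free-energy score) is
    proper.  The defaults comfortably bracket realistic coupling
    uncertainties (Hz) and variance inflations.
    """

    sigma_lo: float = 1e-3
    sigma_hi: float = 10.0
    phi_lo: float = 1.0
    phi_hi: float = 20.0

    def log_prior(self, sigma_B: float, phi_scale: float = 1.0) -> float:
        """ln p(sigma_B) + ln p(phi) for the truncated Jeffreys priors."""
        if not (self.sigma_lo <= sigma_B <= self.sigma_hi):
            return -np.inf
        lp = -np.log(sigma_B) - np.log(np.log(self.sigma_hi / self.sigma_lo))
        if self.phi_hi > self.phi_lo:
            if not (self.phi_lo <= phi_scale <= self.phi_hi):
                return -np.inf
            lp += -np.log(phi_scale) - np.log(np.log(self.phi_hi / self.phi_lo))
        return lp


@dataclass
class UncertaintyState:
    """Nuisance parameters of one observable type.

    sigma_B : Bayesian uncertainty (Hz), > 0.
    phi_scale : variance-scaling parameter >= 1 of the "bad" component.
    """

    sigma_B: float
    phi_scale: float = 1.0

    def __post_init__(self):
        if self.sigma_B <= 0:
            raise ValueError("sigma_B must be positive")
        if self.phi_scale < 1.0:
            raise ValueError("phi_scale must be >= 1")

    def sigma0(self, sem) -> np.ndarray:
        """Per-observable total uncertainty sqrt(sigma_B^2 + sigma_SEM_j^2)."""
        sem = np.asarray(sem, dtype=float)
        return np.sqrt(self.sigma_B**2 + sem**2)


@dataclass
class SeveritySpec:
    """Severity inflators phi_m of the multi-level outlier mixture."""

    phi_levels: np.ndarray

    def __post_init__(self):
        self.phi_levels = np.asarray(self.phi_levels, dtype=float)
        if self.phi_levels.ndim != 1 or self.phi_levels.size < 1:
            raise ValueError("phi_levels must be a nonempty 1-D sequence")
        if self.phi_levels[0] != 1.0:
            raise ValueError("phi_1 must equal 1")
        if np.any(np.diff(self.phi_levels) <= 0):
            raise ValueError("phi_levels must be strictly increasing")

    @property
    def M(self) -> int:
        return self.phi_levels.size


def _mixture_logL(resid, sigma0, sem, phi_levels, log_weights,
                  n_replicas=1, counting="evidence"):
    """Per-observable gated-mixture log data term and softening factor R.

    Returns (logL, R) with logL already carrying the replica counting:
    ``counting="evidence"`` gives N * ln(sum_m w_m N_m);
    ``counting="restraint"`` gives ln(sum_m w_m N_m^N).
    R_j is the mixture-responsibility factor
    ``(sum_m a_m / phi_m^2) / (sum_m a_m)`` by which the outlier mixture
    softens the Gaussian pull in the energy gradient (R = 1 for a single
    unit level).
    """
    resid = np.asarray(resid, dtype=float)
    sem = np.asarray(sem, dtype=float)
    sigma0 = np.broadcast_to(np.asarray(sigma0, dtype=float), resid.shape)
    phi = np.asarray(phi_levels, dtype=float)[:, None]
    logw = np.asarray(log_weights, dtype=float)[:, None]
    if counting not in ("evidence", "restraint"):
        raise ValueError(f"unknown counting {counting!r}")
    rep = n_replicas if counting == "restraint" else 1
    var = (phi * sigma0[None, :]) ** 2
    loga = logw - rep * (0.5 * (_LOG_2PI + np.log(var))
                         + resid[None, :] ** 2 / (2.0 * var))
    # Heaviside gate: drop component m for observable j if sem_j - phi_m*sigma0_j > 0
    loga = np.where(sem[None, :] - phi * sigma0[None, :] > 0, -np.inf, loga)
    m = loga.max(axis=0)
    if np.any(~np.isfinite(m)):
        return np.full(resid.shape, -np.inf), np.ones_like(resid)
    ea = np.exp(loga - m)
    s = ea.sum(axis=0)
    logL = m + np.log(s)
    if counting == "evidence":
        logL = n_replicas * logL
    R = (ea / phi**2).sum(axis=0) / s
    return logL, R


def _check(pred: PredictionSet, data, unc: UncertaintyState):
    d = np.asarray(data, dtype=float)
    if d.shape != pred.g.shape:
        raise ValueError("data and predictions have mismatched shapes")
    sigma0 = unc.sigma0(pred.sem)
    if np.any(sigma0 <= 0):
        raise ValueError("sigma0 must be positive (degenerate likelihood)")
    return d, sigma0


def gaussian_energy(pred: PredictionSet, data, unc: UncertaintyState,
                    prior_energy: float = 0.0,
                    bounds: PriorBounds | None = None,
                    counting: str = "evidence") -> float:
    """Negative log posterior under the Gaussian likelihood (nats).

    u = prior_energy + N * sum_j [ 0.5 ln(2 pi sigma0^2)
                                   + (d_j - g_j)^2 / (2 sigma0^2) ]
        - ln p(sigma_B)

    With ``bounds=None`` the nuisance prior is flat (its term is omitted).
    """
    d, sigma0 = _check(pred, data, unc)
    logL, _ = _mixture_logL(d - pred.g, sigma0, pred.sem, [1.0], [0.0],
                            pred.n_replicas, counting)
    u = prior_energy - logL.sum()
    if bounds is not None:
        u -= bounds.log_prior(unc.sigma_B, 1.0)
    return float(u)


def goodbad_energy(pred: PredictionSet, data, unc: UncertaintyState,
                   prior_energy: float = 0.0,
                   bounds: PriorBounds | None = None,
                   counting: str = "evidence") -> float:
    """Negative log posterior under the two-component outlier mixture (nats).

    Per observable the likelihood is
    ``(1/2) N(d|g, sigma0^2) + (1/(2 phi)) N(d|g, phi^2 sigma0^2)`` with the
    Heaviside gates of the marginalization; equals :func:`gaussian_energy`
    exactly at ``phi = 1``.
    """
    d, sigma0 = _check(pred, data, unc)
    phi = unc.phi_scale
    logL, _ = _mixture_logL(
        d - pred.g, sigma0, pred.sem,
        [1.0, phi], [np.log(0.5), np.log(0.5 / phi)],
        pred.n_replicas, counting,
    )
    u = prior_energy - logL.sum()
    if bounds is not None:
        u -= bounds.log_prior(unc.sigma_B, phi)
    return float(u)


def goodbad_grad_theta(pred: PredictionSet, data, unc: UncertaintyState,
                       fm_gradients, counting: str = "evidence") -> np.ndarray:
    """Analytic gradient of the two-component energy w.r.t. FM parameters.

    fm_gradients : (n_obs, n_params) array of d g_j / d theta_i (for the
    replica-averaged Karplus model these are replica means of the basis
    functions; for a network, backpropagated sensitivities).

    Returns du/dtheta = -N * sum_j (dg_j/dtheta) (d_j - g_j)/sigma0^2 * R_j.
    The gradient treats the prediction spread (SEM) as fixed, the convention
    under which the phi = 1 case is exactly the pure-Gaussian pull.
    """
    d, sigma0 = _check(pred, data, unc)
    grads = np.asarray(fm_gradients, dtype=float)
    if grads.shape[0] != d.size:
        raise ValueError("fm_gradients rows must match the observable count")
    phi = unc.phi_scale
    _, R = _mixture_logL(
        d - pred.g, sigma0, pred.sem,
        [1.0, phi], [np.log(0.5), np.log(0.5 / phi)],
        pred.n_replicas, counting,
    )
    pull = pred.n_replicas * (d - pred.g) / sigma0**2 * R
    return -grads.T @ pull


def multiseverity_energy(pred: PredictionSet, data, unc: UncertaintyState,
                         spec: SeveritySpec,
                         prior_energy: float = 0.0,
                         bounds: PriorBounds | None = None,
                         counting: str = "evidence") -> float:
    """Negative log posterior under the M-level severity mixture (nats).

    Per observable the likelihood is the equal-weight Gaussian scale mixture
    ``(1/M) sum_m H(phi_m sigma0 - sigma_SEM_j) N(d | g, phi_m^2 sigma0^2)``.
    At ``M = 1`` this is exactly the Gaussian model.  Note the two-level case
    deliberately differs from ``good_bad`` by the absent 1/phi factor on the
    wide component; both conventions are implemented as stated.
    """
    d, sigma0 = _check(pred, data, unc)
    logw = np.full(spec.M, -np.log(spec.M))
    logL, _ = _mixture_logL(d - pred.g, sigma0, pred.sem,
                            spec.phi_levels, logw, pred.n_replicas, counting)
    u = prior_energy - logL.sum()
    if bounds is not None:
        u -= bounds.log_prior(unc.sigma_B, 1.0)
    return float(u)
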