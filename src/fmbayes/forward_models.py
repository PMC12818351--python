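"""Karplus forward model and replica-averaged predictions.

The Karplus relation links a vicinal scalar coupling ``J`` (Hz) to the
intervening torsion angle ``phi`` (degrees)::

    J(phi) = A cos^2(phi + phi0) + B cos(phi + phi0) + C

where ``(A, B, C)`` are empirical coefficients and ``phi0`` is a fixed,
coupling-type-specific phase offset.  Ensemble-averaged observables are
modelled by averaging the forward model over ``N`` conformational replicas;
the finite-sampling error of that average is tracked per observable as a
standard error of the mean (SEM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KarplusModel",
    "DihedralEnsemble",
    "PredictionSet",
    "karplus_predict",
    "karplus_gradient",
    "replica_average",
]

#: Phase offsets (degrees) of the six backbone coupling types.
PHASE_OFFSETS = {
    "3J_C_C": 0.0,
    "3J_C_CB": 60.0,
    "3J_HA_C": 120.0,
    "3J_HN_C": 180.0,
    "3J_HN_CB": 60.0,
    "3J_HN_HA": -60.0,
}


@dataclass(frozen=True)
class KarplusModel:
    """One Karplus relation: coefficients in Hz, phase offset in degrees."""

    A: float
    B: float
    C: float
    phi0: float = 0.0
    label: str = "3J"

    def __post_init__(self):
        for name in ("A", "B", "C", "phi0"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"KarplusModel.{name} must be finite, got {v!r}")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C], dtype=float)

    def with_theta(self, theta) -> "KarplusModel":
        A, B, C = np.asarray(theta, dtype=float)
        return KarplusModel(A, B, C, self.phi0, self.label)


def wrap_degrees(phi):
    """Wrap angles into (-180, 180]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = -(np.mod(-phi + 180.0, 360.0) - 180.0)
    return wrapped


@dataclass
class DihedralEnsemble:
    """States x observables matrix of torsion angles with prior populations.

    Parameters
    ----------
    phi : (n_states, n_obs) array, degrees
        One torsion angle per conformational state and observable.
    prior_pop : (n_states,) array
        Prior population p(X) of each state; nonnegative, sums to 1.
    obs_type : (n_obs,) array of str
        Observable-type label of each observable (one Karplus model per type).
    """

    phi: np.ndarray
    prior_pop: np.ndarray | None = None
    obs_type: np.ndarray | None = None

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi angles must be finite")
        n_states, n_obs = self.phi.shape
        if self.prior_pop is None:
            self.prior_pop = np.full(n_states, 1.0 / n_states)
        self.prior_pop = np.asarray(self.prior_pop, dtype=float)
        if self.prior_pop.shape != (n_states,):
            raise ValueError("prior_pop length must equal n_states")
        if np.any(self.prior_pop < 0):
            raise ValueError("prior populations must be nonnegative")
        if abs(self.prior_pop.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"prior populations must sum to 1 (got {self.prior_pop.sum():.6g})"
            )
        if self.obs_type is None:
            self.obs_type = np.array(["3J"] * n_obs)
        self.obs_type = np.asarray(self.obs_type)
        if self.obs_type.shape != (n_obs,):
            raise ValueError("obs_type length must equal n_obs")

    @property
    def n_states(self) -> int:
        return self.phi.shape[0]

    @property
    def n_obs(self) -> int:
        return self.phi.shape[1]

    @property
    def type_labels(self) -> list:
        """Unique type labels in order of first appearance."""
        _, idx = np.unique(self.obs_type, return_index=True)
        return [self.obs_type[i] for i in sorted(idx)]


@dataclass
class PredictionSet:
    """Replica-averaged predictions g_j (Hz) with per-observable SEM."""

    g: np.ndarray
    sem: np.ndarray
    n_replicas: int = 1

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if self.g.shape != self.sem.shape:
            raise ValueError("g and sem must have the same shape")
        if np.any(self.sem < 0):
            raise ValueError("sem must be nonnegative")


def karplus_predict(phi, model: KarplusModel):
    """Evaluate J(phi) = A cos^2(phi+phi0) + B cos(phi+phi0) + C.

    ``phi`` is in degrees; scalar or array, broadcast elementwise.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi must be finite")
    c = np.cos(np.deg2rad(phi + model.phi0))
    return model.A * c * c + model.B * c + model.C


def karplus_gradient(phi, model: KarplusModel):
    """Gradient of J w.r.t. (A, B, C): (cos^2, cos, 1), stacked on the last axis.

    The model is linear in its coefficients, so second derivatives vanish.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi must be finite")
    c = np.cos(np.deg2rad(phi + model.phi0))
    return np.stack([c * c, c, np.ones_like(c)], axis=-1)


def replica_average(replica_states, ensemble: DihedralEnsemble,
                    model: KarplusModel | dict) -> PredictionSet:
    """Average the forward model over replicas and estimate the SEM.

    Parameters
    ----------
    replica_states : sequence of int
        State index occupied by each of the N replicas.
    model : KarplusModel or mapping label -> KarplusModel
        A single relation applied to all observables, or one per type label.

    Returns
    -------
    PredictionSet
        ``g_j`` is the mean prediction over replicas; ``sem_j`` is the
        population standard deviation across replicas divided by sqrt(N),
        so it decreases as the square root of the replica count.
    """
    replica_states = np.asarray(replica_states, dtype=int)
    if replica_states.size == 0:
        raise ValueError("need at least one replica")
    if replica_states.min() < 0 or replica_states.max() >= ensemble.n_states:
        raise ValueError("replica state index out of range")
    n = replica_states.size
    phi = ensemble.phi[replica_states]  # (N, n_obs)
    if isinstance(model, KarplusModel):
        pred = karplus_predict(phi, model)
    else:
        pred = np.empty_like(phi)
        for label, m in model.items():
            mask = ensemble.obs_type == label
            pred[:, mask] = karplus_predict(phi[:, mask], m)
    g = pred.mean(axis=0)
    sem = pred.std(axis=0) / np.sqrt(n)
    return PredictionSet(g=g, sem=sem, n_replicas=n)
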