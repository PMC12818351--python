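"""Tabular input/output, run configuration and manifests.

Formats (plain text throughout):

* ensemble table — CSV/TSV with columns ``state_id, observable_id,
  obs_type, phi_deg`` (one row per state x observable);
* population table — two columns ``state_id, population`` (optional;
  uniform prior populations substituted when absent);
* observables table — columns ``observable_id, obs_type, J_exp_Hz``;
* results and manifests — JSON.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .forward_models import DihedralEnsemble

__all__ = [
    "RunConfig",
    "read_ensemble",
    "write_ensemble",
    "read_observables",
    "write_observables",
    "write_manifest",
    "load_config",
]

_ENSEMBLE_COLS = ["state_id", "observable_id", "obs_type", "phi_deg"]
_OBS_COLS = ["observable_id", "obs_type", "J_exp_Hz"]


@dataclass
class RunConfig:
    """Validated run settings; unknown keys in a config file are rejected."""

    ensemble: str = ""
    observables: str = ""
    populations: str | None = None
    likelihood: str = "good_bad"
    counting: str = "restraint"
    ensemble_average: str = "population"
    sem_in_width: bool = True
    anneal_burn: bool = True
    wls_jumps: bool = True
    n_replicas: int = 32
    n_burn: int = 10_000
    n_steps: int = 50_000
    lrate: float = 1e-4
    eta: float = 0.01
    step_theta: float = 0.02
    step_sigma: float = 0.1
    step_phi: float = 0.1
    sigma_bounds: tuple = (1e-3, 10.0)
    phi_bounds: tuple = (1.0, 20.0)
    severity_levels: tuple | None = None
    xi_count: int = 11
    seed: int = 0
    n_chains: int = 1
    outdir: str = "fmbayes_out"


def load_config(path) -> RunConfig:
    """Read a YAML config; any key outside the schema is an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python",
                       skipinitialspace=True)


def read_ensemble(path, populations_path=None) -> DihedralEnsemble:
    """Load a dihedral ensemble from its tabular representation.

    Rows may come in any order; states and observables are arranged by
    first appearance of their ids.  Prior populations come from the
    optional two-column table and must sum to 1; a missing table means a
    uniform prior.
    """
    df = _read_table(path)
    missing = [c for c in _ENSEMBLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"ensemble table {path} lacks columns {missing}")
    if df[_ENSEMBLE_COLS].isna().any().any():
        bad = df[df[_ENSEMBLE_COLS].isna().any(axis=1)].index[0]
        raise ValueError(f"ensemble table {path}: missing value in row {bad}")
    states = list(dict.fromkeys(df["state_id"]))
    obs = list(dict.fromkeys(df["observable_id"]))
    s_idx = {s: i for i, s in enumerate(states)}
    o_idx = {o: i for i, o in enumerate(obs)}
    phi = np.full((len(states), len(obs)), np.nan)
    obs_type = np.empty(len(obs), dtype=object)
    for row in df.itertuples(index=False):
        phi[s_idx[row.state_id], o_idx[row.observable_id]] = row.phi_deg
        obs_type[o_idx[row.observable_id]] = str(row.obs_type)
    if np.any(np.isnan(phi)):
        s, o = np.argwhere(np.isnan(phi))[0]
        raise ValueError(
            f"ensemble table {path}: no angle for state {states[s]!r}, "
            f"observable {obs[o]!r}")
    prior = None
    if populations_path is not None:
        pdf = _read_table(populations_path)
        if not {"state_id", "population"} <= set(pdf.columns):
            raise ValueError(
                f"population table {populations_path} needs columns "
                "state_id, population")
        pop = dict(zip(pdf["state_id"], pdf["population"].astype(float)))
        absent = [s for s in states if s not in pop]
        if absent:
            raise ValueError(f"populations missing for states {absent}")
        prior = np.array([pop[s] for s in states])
        if abs(prior.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"populations must sum to 1 (got {prior.sum():.6g})")
    ens = DihedralEnsemble(phi=phi, prior_pop=prior,
                           obs_type=obs_type.astype(str))
    ens.state_ids = states
    ens.observable_ids = obs
    return ens


def write_ensemble(path, ensemble: DihedralEnsemble, state_ids=None,
                   observable_ids=None):
    """Write an ensemble in the tabular format (inverse of read_ensemble)."""
    S, D = ensemble.phi.shape
    state_ids = state_ids or getattr(ensemble, "state_ids",
                                     [f"s{i}" for i in range(S)])
    observable_ids = observable_ids or getattr(ensemble, "observable_ids",
                                               [f"obs{j}" for j in range(D)])
    rows = [(state_ids[i], observable_ids[j], ensemble.obs_type[j],
             ensemble.phi[i, j])
            for i in range(S) for j in range(D)]
    pd.DataFrame(rows, columns=_ENSEMBLE_COLS).to_csv(path, index=False)


def read_observables(path, ensemble: DihedralEnsemble | None = None):
    """Load experimental couplings aligned to an ensemble's observables.

    Returns (values, obs_type) ordered like the ensemble when one is given;
    ids absent from the ensemble, or duplicated, are errors.
    """
    df = _read_table(path)
    missing = [c for c in _OBS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"observables table {path} lacks columns {missing}")
    if df["observable_id"].duplicated().any():
        dup = df.loc[df["observable_id"].duplicated(), "observable_id"].tolist()
        raise ValueError(f"duplicate observable ids: {dup}")
    if ensemble is not None and hasattr(ensemble, "observable_ids"):
        ids = list(ensemble.observable_ids)
        have = set(df["observable_id"])
        absent = [o for o in ids if o not in have]
        extra = [o for o in df["observable_id"] if o not in set(ids)]
        if absent or extra:
            raise ValueError(
                f"observable ids do not match the ensemble: missing {absent}, "
                f"unknown {extra}")
        df = df.set_index("observable_id").loc[ids].reset_index()
    return (df["J_exp_Hz"].to_numpy(dtype=float),
            df["obs_type"].to_numpy(dtype=str))


def write_observables(path, observable_ids, obs_type, values):
    pd.DataFrame({
        "observable_id": observable_ids,
        "obs_type": obs_type,
        "J_exp_Hz": values,
    }).to_csv(path, index=False)


def write_manifest(path, config, seeds, extra=None):
    """Atomically write a JSON run manifest (config, seeds, wall time)."""
    payload = {
        "config": asdict(config) if hasattr(config, "__dataclass_fields__")
        else dict(config),
        "seeds": seeds,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        payload.update(extra)
    payload = _jsonable(payload)
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    os.replace(tmp, path)
    return payload


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x
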