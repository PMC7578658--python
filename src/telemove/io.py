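"""Serialization: fitted models to/from JSON, tables to CSV with run metadata."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import HMMFit
from .model import EmissionParams, HMMSpec, TransitionModel


def spec_to_dict(spec: HMMSpec) -> dict:
    em = spec.emissions
    return {
        "n_states": spec.n_states,
        "step_mean": em.step_mean.tolist(),
        "step_sd": em.step_sd.tolist(),
        "angle_mean": em.angle_mean.tolist(),
        "angle_conc": em.angle_conc.tolist(),
        "beta": spec.transitions.beta.tolist(),
        "covariates": list(spec.covariates),
    }


def spec_from_dict(d: dict) -> HMMSpec:
    em = EmissionParams(
        step_mean=np.array(d["step_mean"]),
        step_sd=np.array(d["step_sd"]),
        angle_mean=np.array(d["angle_mean"]),
        angle_conc=np.array(d["angle_conc"]),
    )
    tr = TransitionModel(d["n_states"], np.array(d["beta"]), tuple(d["covariates"]))
    return HMMSpec(em, tr)


def fit_to_json(fit: HMMFit, path, extra: dict | None = None) -> None:
    doc = {
        "spec": spec_to_dict(fit.spec),
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "working": fit.working.tolist(),
        "hessian": None if fit.hessian is None else fit.hessian.tolist(),
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "n_obs": fit.n_obs,
        "start_logliks": fit.start_logliks,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def fit_from_json(path) -> HMMFit:
    d = json.loads(Path(path).read_text())
    return HMMFit(
        spec=spec_from_dict(d["spec"]),
        loglik=d["loglik"],
        n_params=d["n_params"],
        working=np.array(d["working"]),
        hessian=None if d["hessian"] is None else np.array(d["hessian"]),
        converged=d["converged"],
        n_starts=d["n_starts"],
        n_obs=d["n_obs"],
        start_logliks=d.get("start_logliks", []),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path, config: dict | None = None, seed=None) -> None:
    """Write a CSV with an optional '# key=value' metadata comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_sha256={config_hash(config)} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
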