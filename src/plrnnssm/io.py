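"""Delimited-text and JSON round-trips plus run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TrajectoryData
from .model import PLRNNParams
from .observation import obs_params_from_dict
from .training import FitResult, TrainingConfig
from .estep import LatentPosterior

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_fit",
    "read_fit",
    "RunManifest",
    "FIT_SCHEMA_VERSION",
]

FIT_SCHEMA_VERSION = 1


def _read_matrix(path) -> np.ndarray:
    """Delimited text -> float matrix, bit-exact round trip.

    Delimiter is sniffed (tab/comma/whitespace); an optional header row of
    variable names is tolerated.  Parsing goes through Python's float() so
    17-significant-digit output round-trips exactly (pandas' parsers are not
    correctly rounded).
    """
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)

    def split(ln):
        return ln.split(delim) if delim else ln.split()

    start = 0
    try:
        [float(v) for v in split(lines[0])]
    except ValueError:
        start = 1
    ncol = len(split(lines[start]))
    rows = []
    for ln in lines[start:]:
        vals = split(ln)
        if len(vals) != ncol:
            raise ValueError(f"{path}: ragged row ({len(vals)} != {ncol} cols)")
        rows.append([float(v) for v in vals])
    arr = np.array(rows, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{path}: missing or non-finite values")
    return np.atleast_2d(arr)


def read_timeseries(path, inputs_path=None, nuisance_path=None,
                    dt: float = 1.0) -> TrajectoryData:
    """Load X (rows = time points) with optional aligned S and R files."""
    X = _read_matrix(path)
    S = _read_matrix(inputs_path) if inputs_path else None
    R = _read_matrix(nuisance_path) if nuisance_path else None
    for name, mat in (("inputs", S), ("nuisance", R)):
        if mat is not None and mat.shape[0] != X.shape[0]:
            raise ValueError(
                f"{name} rows ({mat.shape[0]}) do not match X rows ({X.shape[0]})")
    return TrajectoryData(X=X, S=S, R=R, dt=dt)


def write_timeseries(path, X: np.ndarray, names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    pd.DataFrame(X, columns=list(names)).to_csv(path, sep="\t", index=False,
                                                float_format="%.17g")


def _cfg_to_dict(cfg: TrainingConfig) -> dict:
    d = asdict(cfg)
    if d.get("hrf_kernel") is not None:
        d["hrf_kernel"] = np.asarray(d["hrf_kernel"]).tolist()
    d["anneal_sigma_levels"] = list(d["anneal_sigma_levels"])
    return d


def write_fit(path, fit: FitResult):
    post = fit.posterior
    payload = {
        "schema_version": FIT_SCHEMA_VERSION,
        "params": fit.params.to_dict(),
        "obs_params": fit.obs_params.to_dict(),
        "posterior": {
            "z_map": post.z_map.tolist(),
            "d_omega": post.d_omega.astype(int).tolist(),
            "cov0": post.cov[0].tolist(),
            "cov1": post.cov[1].tolist() if 1 in post.cov else [],
            "logdet_precision": post.logdet_precision,
        },
        "loglik_trace": [[float(v) for v in tr] for tr in fit.loglik_trace],
        "step_names": fit.step_names,
        "stability_flag": bool(fit.stability_flag),
        "seed": int(fit.seed),
        "final_loglik": float(fit.final_loglik),
        "config": _cfg_to_dict(fit.config) if fit.config else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_fit(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    ver = payload.get("schema_version")
    if ver is None or ver > FIT_SCHEMA_VERSION:
        raise ValueError(
            f"fit file schema version {ver} is newer than supported "
            f"({FIT_SCHEMA_VERSION}); no migration available")
    params = PLRNNParams.from_dict(payload["params"])
    obs = obs_params_from_dict(payload["obs_params"])
    pp = payload["posterior"]
    z_map = np.array(pp["z_map"], dtype=float)
    cov = {0: np.array(pp["cov0"], dtype=float)}
    if pp["cov1"]:
        cov[1] = np.array(pp["cov1"], dtype=float)
    d_omega = np.array(pp["d_omega"], dtype=bool)
    from .estep import _moments_from_gaussian
    Ephi, Ezphi, Ephiphi, Czphi = _moments_from_gaussian(z_map, cov, params.linear)
    post = LatentPosterior(z_map=z_map, d_omega=d_omega, cov=cov, Ephi=Ephi,
                           Ezphi=Ezphi, Ephiphi=Ephiphi, Czphi=Czphi,
                           logdet_precision=float(pp["logdet_precision"]))
    cfg = None
    if payload.get("config"):
        cd = dict(payload["config"])
        if cd.get("hrf_kernel") is not None:
            cd["hrf_kernel"] = np.array(cd["hrf_kernel"])
        cd["anneal_sigma_levels"] = tuple(cd["anneal_sigma_levels"])
        cfg = TrainingConfig(**cd)
    return FitResult(params=params, obs_params=obs, posterior=post,
                     loglik_trace=payload["loglik_trace"],
                     step_names=payload["step_names"],
                     stability_flag=payload["stability_flag"],
                     config=cfg, seed=payload["seed"],
                     final_loglik=payload["final_loglik"])


class RunManifest:
    """Reproducibility record written next to every CLI output."""

    def __init__(self, command: str, config: dict, seed: int,
                 inputs: dict | None = None, outputs: list | None = None):
        self.command = command
        self.config = config
        self.seed = seed
        self.inputs = inputs or {}
        self.outputs = outputs or []

    @staticmethod
    def digest(path) -> str:
        hsh = hashlib.sha256()
        hsh.update(Path(path).read_bytes())
        return hsh.hexdigest()

    def to_dict(self) -> dict:
        from . import __version__
        return {
            "command": self.command,
            "config": self.config,
            "master_seed": self.seed,
            "input_digests": {k: self.digest(v) for k, v in self.inputs.items()},
            "outputs": [str(p) for p in self.outputs],
            "package_version": __version__,
            "python": platform.python_version(),
        }

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
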