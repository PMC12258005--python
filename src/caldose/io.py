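"""File round-tripping: cohort dumps, estimate tables, run manifests.

Cohorts are written as one TSV patient table plus .npy array stacks
(planned/delivered dose, ground-truth arrays, outcome noise), tied
together by a JSON manifest recording the config, seed, package version
and per-file checksums.  A manifest plus the code version suffices to
regenerate every output.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, EstimandArrays
from .config import SimulationConfig
from .estimators import EffectEstimate

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_estimates",
    "load_estimate",
    "IntegrityError",
]

_COHORT_ARRAYS = ("dose_planned", "dose_delivered", "theta", "xi", "u_y")


class IntegrityError(RuntimeError):
    """A stored file does not match its manifest checksum."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({
        "patient_id": np.arange(cohort.n_obs),
        "C": cohort.C,
        "V_O": cohort.V_O,
        "M_O": cohort.M_O,
        "V_T": cohort.V_T,
        "tumor_i": cohort.tumor_centers[:, 0],
        "tumor_j": cohort.tumor_centers[:, 1],
        "Y": cohort.Y,
    })
    table.to_csv(out / "patients.tsv", sep="\t", index=False)
    arrays = {
        "dose_planned": cohort.D_plan,
        "dose_delivered": cohort.D_del,
        "theta": cohort.estimands.theta,
        "xi": cohort.estimands.xi,
        "u_y": cohort.U_Y,
    }
    for name, arr in arrays.items():
        np.save(out / f"{name}.npy", arr)
    files = ["patients.tsv"] + [f"{n}.npy" for n in _COHORT_ARRAYS]
    manifest = {
        "kind": "cohort",
        "package_version": __version__,
        "config": cohort.config.to_dict(),
        "seed": cohort.config.seed,
        "files": {f: _sha256(out / f) for f in files},
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return mpath


def load_cohort(in_dir, verify: bool = True) -> Cohort:
    """Read a cohort dump back; verifies checksums unless disabled."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("kind") != "cohort":
        raise ValueError(f"{src} is not a cohort dump")
    if verify:
        for fname, digest in manifest["files"].items():
            actual = _sha256(src / fname)
            if actual != digest:
                raise IntegrityError(f"checksum mismatch for {fname} in {src}")
    config = SimulationConfig.from_dict(manifest["config"])
    table = pd.read_csv(src / "patients.tsv", sep="\t", float_precision="round_trip")
    arrays = {n: np.load(src / f"{n}.npy") for n in _COHORT_ARRAYS}
    return Cohort(
        config=config,
        C=table["C"].to_numpy(),
        V_O=table["V_O"].to_numpy(),
        M_O=table["M_O"].to_numpy(),
        V_T=table["V_T"].to_numpy(),
        tumor_centers=table[["tumor_i", "tumor_j"]].to_numpy(dtype=int),
        D_plan=arrays["dose_planned"],
        D_del=arrays["dose_delivered"],
        U_Y=arrays["u_y"],
        Y=table["Y"].to_numpy(),
        estimands=EstimandArrays(theta=arrays["theta"], xi=arrays["xi"]),
    )


def save_estimates(
    estimates: Sequence[EffectEstimate],
    out_dir,
    repetition: int = 0,
) -> Path:
    """Write effect estimates as one long-format TSV
    (method, repetition, i, j, theta_hat, converged) plus per-method .npy
    arrays; returns the table path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: List[Dict] = []
    for est in estimates:
        if est.theta_hat is not None:
            arr = np.asarray(est.theta_hat)
            np.save(out / f"theta_hat_{est.method}.npy", arr)
            for (i, j), v in np.ndenumerate(arr):
                rows.append({
                    "method": est.method, "repetition": repetition,
                    "i": i, "j": j, "theta_hat": v, "converged": est.converged,
                })
        else:
            rows.append({
                "method": est.method, "repetition": repetition,
                "i": -1, "j": -1, "theta_hat": np.nan, "converged": est.converged,
            })
    path = out / "estimates.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def load_estimate(in_dir, method: str) -> np.ndarray:
    return np.load(Path(in_dir) / f"theta_hat_{method}.npy")
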