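"""File formats: response/Q-matrix CSV, truth and manifest JSON, and a
posterior draw store.

CSV dialect: comma-separated, UTF-8, one header row.  Response files
are person-major (one row per person, one column per item) with
missing responses as empty cells.  Q-matrix files carry an ``item_id``
first column so custom labels round-trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .mcmc import McmcConfig, PosteriorDraws, PriorSpec
from .model_core import QMatrix, ResponseMatrix

__all__ = [
    "write_response_csv",
    "read_response_csv",
    "write_qmatrix_csv",
    "read_qmatrix_csv",
    "write_json",
    "write_manifest",
    "save_draws",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_response_csv(path, responses: ResponseMatrix, item_ids=None) -> None:
    n_items = responses.n_items
    cols = list(item_ids) if item_ids is not None else [f"I{i + 1}" for i in range(n_items)]
    vals = np.where(responses.mask, responses.entries, np.nan)
    df = pd.DataFrame(vals, columns=cols).astype("Int64")
    df.to_csv(path, index=False)


def read_response_csv(path) -> ResponseMatrix:
    df = pd.read_csv(path)
    return ResponseMatrix(df.to_numpy(dtype=float))


def write_qmatrix_csv(path, q: QMatrix) -> None:
    df = pd.DataFrame(q.entries, columns=q.attribute_ids)
    df.insert(0, "item_id", q.item_ids)
    df.to_csv(path, index=False)


def read_qmatrix_csv(path) -> QMatrix:
    df = pd.read_csv(path)
    if "item_id" in df.columns:
        item_ids = [str(v) for v in df.pop("item_id")]
    else:
        item_ids = None
    return QMatrix(df.to_numpy(dtype=int), item_ids=item_ids,
                   attribute_ids=tuple(df.columns))


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, seed, config: Dict,
                   inputs: Optional[Dict[str, Path]] = None,
                   outputs: Optional[Dict[str, Path]] = None) -> None:
    """Record everything needed to reproduce a run: command, seed,
    full configuration, package version and content hashes of the
    files read and written."""
    manifest = {
        "package": "pincdm",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                   for k, p in (inputs or {}).items()},
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in (outputs or {}).items()},
    }
    write_json(path, manifest)


def save_draws(directory, draws: PosteriorDraws, store_thin: int = 1) -> None:
    """Persist retained draws to one CSV per parameter block per chain
    plus a JSON manifest (config, priors, acceptance rates).

    ``store_thin`` subsamples the retained draws for storage only;
    person-level blocks can be large at full scale.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "model_tag": draws.model_tag,
        "n_chains": draws.n_chains,
        "n_draws": draws.n_draws,
        "store_thin": store_thin,
        "acceptance": draws.acceptance,
        "config": {
            "n_chains": draws.config.n_chains, "n_iter": draws.config.n_iter,
            "n_burn": draws.config.n_burn, "n_thin": draws.config.n_thin,
            "seed": _seed_repr(draws.config.seed),
        },
        "priors": {
            "delta_shapes": draws.priors.delta_shapes,
            "slip_shapes": draws.priors.slip_shapes,
            "guess_shapes": draws.priors.guess_shapes,
            "lambda_sd": draws.priors.lambda_sd,
            "beta_sd": draws.priors.beta_sd,
        },
        "blocks": {},
    }
    for name, arr in draws.draws.items():
        shape = arr.shape[2:]
        meta["blocks"][name] = list(shape)
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)[:, ::store_thin, :]
        cols = _flat_labels(name, shape)
        for c in range(flat.shape[0]):
            pd.DataFrame(flat[c], columns=cols).to_csv(
                directory / f"chain{c + 1}_{name}.csv", index=False
            )
    write_json(directory / "draws_manifest.json", meta)


def _seed_repr(seed):
    if isinstance(seed, np.random.SeedSequence):
        return {"entropy": seed.entropy, "spawn_key": list(seed.spawn_key)}
    return seed


def _flat_labels(name, shape):
    if not shape:
        return [name]
    idx = np.indices(shape).reshape(len(shape), -1).T + 1
    return [name + "[" + ",".join(map(str, row)) + "]" for row in idx]
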