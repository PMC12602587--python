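"""Serialization of models (JSON) and binary datasets (CSV + sidecar JSON).

Model JSON: ``{"m": int, "tau": [...], "omega": [[...]]}``; readers validate
symmetry, zero diagonal and finiteness.  Datasets are plain CSV with a
``v1..vm`` header and 0/1 entries; the selection cutoff and sampling seed
live in a ``<name>.meta.json`` sidecar so the table itself stays a clean
rectangle.  Floats survive round-trips bit-exactly (repr-based JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NonBinaryError, RowBelowCutoffError, ValidationError
from .model import IsingModel
from .sampling import BinaryDataset

__all__ = ["write_model", "read_model", "write_dataset", "read_dataset"]


def write_model(model: IsingModel, path) -> None:
    doc = {"m": model.m, "tau": model.tau.tolist(), "omega": model.omega.tolist()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> IsingModel:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("tau", "omega"):
        if key not in doc:
            raise ValidationError(f"model file {path} missing field {key!r}")
    tau = np.asarray(doc["tau"], dtype=float)
    omega = np.asarray(doc["omega"], dtype=float)
    if "m" in doc and doc["m"] != tau.shape[0]:
        raise ValidationError(
            f"model file {path}: declared m={doc['m']} but tau has length "
            f"{tau.shape[0]}"
        )
    return IsingModel(tau, omega)  # constructor validates symmetry etc.


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_dataset(dataset: BinaryDataset, path) -> None:
    cols = [f"v{i + 1}" for i in range(dataset.m)]
    pd.DataFrame(dataset.data, columns=cols).to_csv(path, index=False)
    meta = {"cutoff": dataset.cutoff, "seed": dataset.seed}
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_dataset(path, cutoff=None) -> BinaryDataset:
    """Read a CSV dataset; validates 0/1 entries and row sums vs the cutoff.

    ``cutoff`` overrides the sidecar value when given.
    """
    df = pd.read_csv(path)
    values = df.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise NonBinaryError(
            f"{path}: entry {values[r, c]!r} at row {r}, column {df.columns[c]!r} "
            "is not 0/1"
        )
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        with open(mp) as fh:
            meta = json.load(fh)
    if cutoff is None:
        cutoff = meta.get("cutoff")
    try:
        return BinaryDataset(
            values.astype(np.int8), cutoff=cutoff, seed=meta.get("seed")
        )
    except RowBelowCutoffError as exc:
        raise RowBelowCutoffError(f"{path}: {exc}") from exc
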