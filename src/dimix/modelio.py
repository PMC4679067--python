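"""Reading and writing models, posterior draws, and data matrices.

Model JSON schema (version 1)::

    {
      "schema_version": 1,
      "dim": p,
      "components": [{"weight": w, "mean": [...], "cov": [[...], ...]}, ...],
      "partition": [c_1, ..., c_J],
      "alpha": {"1": a_1, ...}
    }

Matrices are row-major nested lists.  ``alpha`` is redundant (derivable from
weights and partition) but stored for human inspection; it is validated, not
trusted, on load.  Posterior draws are stored as JSON lines, one model object
per line, with a header line carrying the schema version.

Data matrices are delimited text with a header row; missing values are
rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fit import PosteriorDraws
from .mixture import GaussianComponent, StructuredMixture

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "save_draws",
    "load_draws",
    "load_data",
    "save_data",
]

SCHEMA_VERSION = 1


def model_to_dict(mix: StructuredMixture) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "dim": mix.dim,
        "components": [
            {"weight": c.weight, "mean": c.mean.tolist(), "cov": c.cov.tolist()}
            for c in mix.components
        ],
        "partition": list(mix.partition),
        "alpha": {str(c): mix.alpha(c) for c in mix.labels},
    }


def model_from_dict(d: dict) -> StructuredMixture:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    comps = [
        GaussianComponent(entry["mean"], entry["cov"], entry["weight"])
        for entry in d["components"]
    ]
    mix = StructuredMixture(comps, d.get("partition"))
    if mix.dim != d["dim"]:
        raise ValueError("model dim field disagrees with component dimensions")
    stored_alpha = d.get("alpha")
    if stored_alpha is not None:
        for c, a in stored_alpha.items():
            if abs(mix.alpha(int(c)) - float(a)) > 1e-6:
                raise ValueError(f"stored alpha for subpopulation {c} disagrees with weights")
    return mix


def save_model(mix: StructuredMixture, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(mix), indent=1))


def load_model(path) -> StructuredMixture:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_draws(draws: PosteriorDraws, path) -> None:
    with open(path, "w") as fh:
        header = {
            "schema_version": SCHEMA_VERSION,
            "aligned": draws.aligned,
            "n_draws": len(draws),
        }
        fh.write(json.dumps(header) + "\n")
        for mix in draws:
            fh.write(json.dumps(model_to_dict(mix)) + "\n")


def load_draws(path) -> PosteriorDraws:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported draws schema version")
        draws = [model_from_dict(json.loads(line)) for line in fh if line.strip()]
    return PosteriorDraws(draws=draws, aligned=bool(header.get("aligned", False)))


def load_data(path, sep=None) -> tuple[np.ndarray, list[str]]:
    """Load a delimited numeric matrix with a header row.

    The delimiter is sniffed (comma/tab/whitespace) unless given.  Missing or
    non-numeric entries are rejected with the offending columns named.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric columns in {path}: {bad}")
    if df.isna().any().any():
        cols = list(df.columns[df.isna().any()])
        raise ValueError(f"missing values in {path}, columns {cols}")
    return df.to_numpy(dtype=float), list(df.columns)


def save_data(x: np.ndarray, path, columns: Iterable[str] | None = None) -> None:
    x = np.atleast_2d(x)
    if columns is None:
        columns = [f"x{i}" for i in range(1, x.shape[1] + 1)]
    pd.DataFrame(x, columns=list(columns)).to_csv(path, index=False)
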