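"""Reading and writing community parameters, trajectories, and spectra.

Matrices travel as headered CSV/TSV (first column = resource labels,
header row = consumer labels), vectors as single-column CSV, and a full
parameter set as a YAML (or JSON) document whose matrix/vector entries
are either file references (relative to the document) or inline lists.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from numpy.typing import ArrayLike, NDArray

from .params import CommunityParameters, Trajectory
from .stability import Spectrum


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_matrix(path: str | Path) -> NDArray[np.float64]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return df.to_numpy(dtype=float)


def write_matrix(
    path: str | Path,
    M: ArrayLike,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> None:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    rows = row_labels or [f"resource_{i + 1}" for i in range(M.shape[0])]
    cols = col_labels or [f"consumer_{j + 1}" for j in range(M.shape[1])]
    path = Path(path)
    pd.DataFrame(M, index=rows, columns=cols).to_csv(path, sep=_sep(path))


def read_vector(path: str | Path) -> NDArray[np.float64]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    return df.iloc[:, -1].to_numpy(dtype=float)


def write_vector(path: str | Path, v: ArrayLike, name: str = "value") -> None:
    v = np.atleast_1d(np.asarray(v, dtype=float))
    path = Path(path)
    pd.DataFrame({name: v}).to_csv(path, sep=_sep(path), index=False)


def _resolve_array(entry: Any, base: Path, kind: str) -> NDArray[np.float64] | None:
    if entry is None:
        return None
    if isinstance(entry, str):
        reader = read_matrix if kind == "matrix" else read_vector
        return reader(base / entry)
    return np.asarray(entry, dtype=float)


def load_parameters(path: str | Path) -> CommunityParameters:
    """Load a community from a YAML/JSON parameter document.

    Recognized keys: ``C`` (required), ``rho``, ``mu`` (required),
    ``P``, ``eta`` (optional), ``epsilon`` (scalar, default 1).  Array
    values may be file paths (resolved relative to the document) or
    inline lists.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    base = path.parent
    return CommunityParameters(
        C=_resolve_array(doc["C"], base, "matrix"),
        P=_resolve_array(doc.get("P"), base, "matrix"),
        rho=_resolve_array(doc["rho"], base, "vector"),
        mu=_resolve_array(doc["mu"], base, "vector"),
        eta=_resolve_array(doc.get("eta"), base, "vector"),
        epsilon=float(doc.get("epsilon", 1.0)),
    )


def save_parameters(path: str | Path, params: CommunityParameters) -> None:
    """Write a self-contained (inline-array) YAML parameter document."""
    doc = {
        "C": params.C.tolist(),
        "rho": params.rho.tolist(),
        "mu": params.mu.tolist(),
        "epsilon": params.epsilon,
    }
    if params.has_production:
        doc["P"] = params.P.tolist()
    if np.any(params.eta != 0):
        doc["eta"] = params.eta.tolist()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Tidy CSV with columns ``time, variable, value``."""
    records = []
    for k, t in enumerate(traj.times):
        for i in range(traj.R.shape[1]):
            records.append((t, f"R_{i + 1}", traj.R[k, i]))
        for j in range(traj.S.shape[1]):
            records.append((t, f"S_{j + 1}", traj.S[k, j]))
    pd.DataFrame(records, columns=["time", "variable", "value"]).to_csv(
        path, index=False
    )


def write_spectrum_csv(path: str | Path, spec: Spectrum) -> None:
    pd.DataFrame(
        {"re": spec.eigenvalues.real, "im": spec.eigenvalues.imag}
    ).to_csv(path, index=False)


def spectrum_summary(spec: Spectrum) -> dict:
    return {
        "max_real": spec.max_real,
        "stable": spec.stable,
        "marginal": spec.marginal,
        "n_eigenvalues": int(spec.eigenvalues.shape[0]),
        "tol": spec.tol,
    }


def write_json(path: str | Path, obj: Any) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_, np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
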