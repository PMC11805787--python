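"""Plain-text persistence: CSV tables, TSV matrices, edge lists, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table", "read_table",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_edge_list", "read_edge_list",
    "write_json", "read_json",
]


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)


def write_matrix_tsv(matrix: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.12g")


def read_matrix_tsv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_edge_list(matrix: np.ndarray, path) -> None:
    """Whitespace `i j weight` upper-triangle edge list (0-based nodes)."""
    m = np.asarray(matrix, dtype=float)
    iu, ju = np.triu_indices(m.shape[0], k=1)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(f"{i} {j} {m[i, j]:.12g}\n")


def read_edge_list(path, n_nodes: int | None = None) -> np.ndarray:
    rows = np.loadtxt(path, ndmin=2)
    n = n_nodes or int(rows[:, :2].max()) + 1
    m = np.zeros((n, n))
    for i, j, w in rows:
        m[int(i), int(j)] = m[int(j), int(i)] = w
    return m


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonable)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
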