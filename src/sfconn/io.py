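"""Delimited-text I/O for connectivity matrices, node tables and edge lists.

Matrices travel as TSV with a header row/column of node ids plus an optional
JSON sidecar carrying the matrix kind. Node indexing is 0-based internally;
files carry explicit ids so external 1-based conventions are absorbed at the
boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_KINDS = ("count", "correlation", "length", "metric")

__all__ = [
    "ConnectivityMatrix",
    "load_matrix",
    "save_matrix",
    "save_edge_list",
    "load_node_table",
    "save_node_table",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk table violates the matrix/node-table contract."""


@dataclass
class ConnectivityMatrix:
    """Square symmetric edge-weight matrix with ordered node ids.

    kind: 'count' (streamlines), 'correlation' (FC), 'length' (inverse
    counts / mm) or 'metric' (any derived edgewise quantity).
    """

    values: np.ndarray
    node_ids: list = field(default=None)
    kind: str = "metric"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(f"matrix must be square, got shape {self.values.shape}")
        if self.kind not in VALID_KINDS:
            raise FormatError(f"unknown kind {self.kind!r}; expected one of {VALID_KINDS}")
        n = self.values.shape[0]
        if self.node_ids is None:
            self.node_ids = list(range(n))
        if len(self.node_ids) != n:
            raise FormatError(f"{len(self.node_ids)} node ids for {n}x{n} matrix")
        if self.kind in ("count", "correlation"):
            finite = np.isfinite(self.values)
            asym = np.abs(np.where(finite, self.values, 0.0)
                          - np.where(finite.T, self.values.T, 0.0)).max() if n else 0.0
            if asym > 1e-9:
                raise FormatError(f"{self.kind} matrix asymmetric by {asym:g} (> 1e-9)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.values.copy(), list(self.node_ids), self.kind)


def load_matrix(path, kind: str = "metric") -> ConnectivityMatrix:
    """Read a TSV matrix (header row + index column of node ids).

    Symmetry is enforced by averaging with the transpose when the maximum
    asymmetry is below 1e-6; larger asymmetry is an error. NaN cells are
    reported with their coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: non-square table {values.shape[0]}x{values.shape[1]}")
    nan_rows, nan_cols = np.nonzero(np.isnan(values))
    if nan_rows.size:
        cells = ", ".join(f"({i},{j})" for i, j in zip(nan_rows[:5], nan_cols[:5]))
        raise FormatError(f"{path}: NaN entries at cells {cells}")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym >= 1e-6:
        raise FormatError(f"{path}: asymmetry {asym:g} exceeds 1e-6")
    values = (values + values.T) / 2.0
    side = path.with_suffix(path.suffix + ".json")
    if kind == "metric" and side.exists():
        meta = json.loads(side.read_text())
        kind = meta.get("kind", kind)
    return ConnectivityMatrix(values, list(df.columns), kind)


def save_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write a matrix as TSV plus a JSON sidecar with its kind."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.node_ids, columns=matrix.node_ids)
    df.to_csv(path, sep="\t")
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps({"kind": matrix.kind, "n_nodes": matrix.n_nodes}))


def save_edge_list(matrix: ConnectivityMatrix, path) -> None:
    """Write nonzero upper-triangle edges as `i<TAB>j<TAB>weight`, 0-based."""
    i, j = np.triu_indices(matrix.n_nodes, k=1)
    w = matrix.values[i, j]
    keep = w != 0
    df = pd.DataFrame({"i": i[keep], "j": j[keep], "weight": w[keep]})
    df.to_csv(path, sep="\t", index=False)


def load_node_table(path) -> pd.DataFrame:
    """Read a node table: node_id, label, hemisphere, x, y, z (mm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "label", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: node table missing columns {sorted(missing)}")
    if df["node_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate node ids")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise FormatError(f"{path}: non-finite coordinates")
    return df


def save_node_table(nodes: pd.DataFrame, path) -> None:
    nodes.to_csv(path, sep="\t", index=False)
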