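"""Edgewise communication metrics and analytic functional connectivity.

Implements the structural predictors of functional connectivity:

* weighted shortest-path length — edge length is the inverse streamline
  count, path length the minimal summed length (Dijkstra);
* search information — the number of bits (-log2 probability) a random
  walker needs to follow the shortest path; the default walker cannot
  immediately backtrack (``no_return``), a memoryless variant is provided;
* path transitivity — mean weighted matching index over node pairs of the
  shortest path, i.e. the density of one-step detours along the path;
* Euclidean distance between region centres;
* analytic functional connectivity (FCA) — the stationary correlation of a
  linear system with leak -I and coupling c*W, Cov = (I - c W)^-1, with W
  normalised by its largest eigenvalue so the coupling c is dimensionless
  and admissible for c in (0, 1);
* coupling fit — grid search for the c maximising the Pearson correlation
  between FCA of a (group-averaged) structural connectome and empirical FC.

Shortest paths are tie-broken deterministically: among equal-length paths
the lexicographically smallest node sequence is stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import pearsonr

from .io import ConnectivityMatrix

__all__ = [
    "MetricSet", "CouplingFit", "edge_lengths", "shortest_paths",
    "search_information", "path_transitivity", "euclidean_distance",
    "matching_index_matrix", "fca", "fit_coupling", "compute_metrics",
    "SpectralConditionError",
]


class SpectralConditionError(ValueError):
    """Coupling too strong: I - cW is not positive definite."""


@dataclass
class MetricSet:
    """Bundle of edgewise structural metrics sharing one node order."""

    pl: ConnectivityMatrix
    si: ConnectivityMatrix          # symmetrised: mean of the two directions
    pt: ConnectivityMatrix
    ed: ConnectivityMatrix = None
    fca: ConnectivityMatrix = None
    logcount: ConnectivityMatrix = None
    si_directed: np.ndarray = None  # SI[i, j] for the walk i -> j
    shortest_path_nodes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"pl": self.pl, "si": self.si, "pt": self.pt}
        if self.ed is not None:
            out["ed"] = self.ed
        if self.fca is not None:
            out["fca"] = self.fca
        if self.logcount is not None:
            out["logcount"] = self.logcount
        return out


@dataclass
class CouplingFit:
    c_hat: float
    curve: np.ndarray               # columns (c, pearson r)
    c_max_admissible: float


def edge_lengths(W: np.ndarray) -> np.ndarray:
    """Length matrix L_ij = 1 / W_ij; absent edges are infinite."""
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("negative weights are not valid streamline counts")
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_paths(L: np.ndarray) -> tuple:
    """All-pairs weighted shortest paths with lexicographic tie-breaking.

    Returns (pl, paths): pl[i, j] the minimal summed length (inf when
    disconnected) and paths a dict mapping each ordered pair (s, t) to the
    node tuple of the stored shortest path. Among equal-length paths the
    lexicographically smallest node sequence is chosen, by greedy descent:
    at node u take the smallest-index neighbour v with
    L[u, v] + d(v, t) == d(u, t).
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    adj = np.where(np.isfinite(L), L, 0.0)
    np.fill_diagonal(adj, 0.0)
    D = dijkstra(csr_matrix(adj), directed=False)
    finite = np.isfinite(L) & ~np.eye(n, dtype=bool)
    paths = {}
    idx = np.arange(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(D[s, t]):
                continue
            path = [s]
            u = s
            while u != t:
                slack = L[u] + D[:, t] - D[u, t]
                ok = finite[u] & (np.abs(slack) <= 1e-9 * max(1.0, D[u, t]))
                cand = idx[ok]
                u = int(cand[0])
                path.append(u)
                if len(path) > n:
                    raise RuntimeError("path reconstruction failed to terminate")
            paths[(s, t)] = tuple(path)
    return D, paths


def search_information(W: np.ndarray, paths: dict, variant: str = "no_return") -> np.ndarray:
    """SI[s, t] = -log2 probability that a walker follows the stored path.

    Step probability at node k is w(k, next) over the outgoing strength of k;
    under ``no_return`` the strength excludes the edge just traversed, under
    ``memoryless`` it is the full nodal strength.
    """
    if variant not in ("no_return", "memoryless"):
        raise ValueError(f"unknown variant {variant!r}")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    S = W.sum(axis=1)
    si = np.full((n, n), np.inf)
    np.fill_diagonal(si, 0.0)
    log2 = np.log(2.0)
    for (s, t), path in paths.items():
        logp = 0.0
        for step in range(len(path) - 1):
            u, v = path[step], path[step + 1]
            denom = S[u]
            if variant == "no_return" and step > 0:
                denom = denom - W[path[step - 1], u]
            if denom <= 0:
                raise ValueError(f"zero outgoing strength at node {u}; cannot normalise")
            logp += np.log(W[u, v] / denom)
        si[s, t] = -logp / log2
    return si


def matching_index_matrix(W: np.ndarray) -> np.ndarray:
    """Weighted matching index m_uv: shared-neighbour weight fraction.

    m_uv = sum over common neighbours k of (w_uk + w_vk), divided by the
    total weight incident to u or v excluding the direct u-v edge. Zero when
    the pair has no shared neighbours or no other edges at all.
    """
    W = np.asarray(W, dtype=float)
    A = (W > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    WA = W @ A
    num = WA + WA.T
    S = W.sum(axis=1)
    den = S[:, None] + S[None, :] - 2.0 * W
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(M, 0.0)
    return M


def path_transitivity(W: np.ndarray, paths: dict) -> np.ndarray:
    """PT[s, t] = mean matching index over node pairs of the stored path."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    M = matching_index_matrix(W)
    pt = np.zeros((n, n))
    done = set()
    for (s, t), path in paths.items():
        if (t, s) in done:
            pt[s, t] = pt[t, s]
            continue
        nodes = np.asarray(path)
        k = nodes.size
        sub = M[np.ix_(nodes, nodes)]
        iu = np.triu_indices(k, 1)
        pt[s, t] = pt[t, s] = float(sub[iu].mean()) if iu[0].size else 0.0
        done.add((s, t))
    return pt


def euclidean_distance(nodes: pd.DataFrame) -> np.ndarray:
    """Straight-line distance in mm between region centres."""
    xyz = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError("non-finite coordinates")
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _normalise_w(W: np.ndarray) -> tuple:
    """W / largest eigenvalue, plus the admissible coupling bound 1/rho."""
    eig = np.linalg.eigvalsh(W)
    lam_max = eig[-1]
    if lam_max <= 0:
        raise ValueError("largest eigenvalue non-positive; empty connectome?")
    Wn = W / lam_max
    rho = max(abs(eig[0]), eig[-1]) / lam_max
    return Wn, 1.0 / rho


def fca(W: np.ndarray, c: float) -> np.ndarray:
    """Analytic FC: correlation matrix of Cov = (I - c W~)^-1.

    W~ is W normalised by its largest eigenvalue; the model is admissible
    while the spectral radius of c W~ stays below 1.
    """
    if c < 0:
        raise ValueError("coupling must be non-negative")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    Wn, c_max = _normalise_w(W) if c > 0 else (W, np.inf)
    if c >= c_max:
        raise SpectralConditionError(
            f"coupling c={c:g} violates the spectral condition; admissible c < {c_max:g}")
    cov = np.linalg.inv(np.eye(n) - c * Wn)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def fit_coupling(W_avg: np.ndarray, FC_avg: np.ndarray, grid=None) -> CouplingFit:
    """Grid-search the coupling maximising corr(upper-tri FCA, upper-tri FC).

    c = 0 is a degenerate boundary (FCA is the identity, the off-diagonal
    predictor has zero variance) and is excluded from the default grid.
    """
    W_avg = np.asarray(W_avg, dtype=float)
    _, c_max = _normalise_w(W_avg)
    if grid is None:
        grid = np.arange(0.01, min(0.99, c_max - 1e-6), 0.01)
    grid = np.asarray([c for c in np.atleast_1d(grid) if 0 < c < c_max])
    if grid.size == 0:
        raise ValueError("no admissible coupling values in grid")
    iu = np.triu_indices(W_avg.shape[0], 1)
    fc_u = np.asarray(FC_avg, dtype=float)[iu]
    rs = np.empty(grid.size)
    for k, c in enumerate(grid):
        rs[k] = pearsonr(fca(W_avg, float(c))[iu], fc_u)[0]
    best = int(np.argmax(rs))
    return CouplingFit(float(grid[best]), np.column_stack([grid, rs]), float(c_max))


def compute_metrics(sc: ConnectivityMatrix, nodes: pd.DataFrame = None,
                    coupling: float = None, si_variant: str = "no_return") -> MetricSet:
    """All edgewise metrics of a structural connectome in one pass."""
    W = sc.values
    L = edge_lengths(W)
    pl, paths = shortest_paths(L)
    si_dir = search_information(W, paths, variant=si_variant)
    si_sym = (si_dir + si_dir.T) / 2.0
    pt = path_transitivity(W, paths)
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.where(W > 0, np.log(np.where(W > 0, W, 1.0)), np.nan)
    np.fill_diagonal(logc, 0.0)
    mk = lambda v: ConnectivityMatrix(v, list(sc.node_ids), "metric")
    ms = MetricSet(
        pl=mk(pl), si=mk(si_sym), pt=mk(pt),
        logcount=mk(logc), si_directed=si_dir, shortest_path_nodes=paths,
    )
    if nodes is not None:
        ms.ed = mk(euclidean_distance(nodes))
    if coupling is not None:
        ms.fca = ConnectivityMatrix(fca(W, coupling), list(sc.node_ids), "correlation")
    return ms
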