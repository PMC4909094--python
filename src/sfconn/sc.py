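"""Structural connectome construction from dual tractography-run count matrices.

Each subject contributes two streamline-count matrices (independent
tractography runs from random seeds). Edges are kept only when reproducible
across runs: an edge is excluded if either run saw zero streamlines, or if
the run difference exceeds three standard deviations of the difference
distribution over that subject's connectome. Surviving weights are the sum
of the two runs, preserving count semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConnectivityMatrix

__all__ = ["ReconciledSC", "reconcile_runs", "group_average", "threshold_top_fraction", "sparsity"]


def _upper(n: int):
    return np.triu_indices(n, k=1)


def sparsity(values: np.ndarray) -> float:
    """Fraction of upper-triangle node pairs with a nonzero connection."""
    iu = _upper(values.shape[0])
    w = values[iu]
    return float(np.count_nonzero(w)) / w.size


@dataclass
class ReconciledSC:
    """Reconciled per-subject structural connectome with exclusion bookkeeping."""

    weights: ConnectivityMatrix
    excluded_zero: set = field(default_factory=set)  # (i, j), i < j
    excluded_sd: set = field(default_factory=set)
    sparsity: float = 0.0
    sigma_d: float = 0.0
    # sigma_d is computed over both-nonzero edges only: zero-in-one-run edges
    # are removed by the first rule and would otherwise inflate the spread.
    metadata: dict = field(default_factory=dict)


def reconcile_runs(run1: ConnectivityMatrix, run2: ConnectivityMatrix) -> ReconciledSC:
    """Merge two tractography runs with zero- and 3-SD exclusion rules."""
    a, b = run1.values, run2.values
    if a.shape != b.shape:
        raise ValueError(f"run shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    iu = _upper(n)
    a_u, b_u = a[iu], b[iu]

    zero_mask = (np.minimum(a_u, b_u) == 0) & ((a_u > 0) | (b_u > 0))
    both = (a_u > 0) & (b_u > 0)
    diffs = a_u[both] - b_u[both]
    sigma_d = float(np.std(diffs)) if diffs.size else 0.0
    sd_mask = both & (np.abs(a_u - b_u) > 3.0 * sigma_d) if sigma_d > 0 else np.zeros_like(both)

    keep = both & ~sd_mask
    w_u = np.where(keep, a_u + b_u, 0.0)
    w = np.zeros_like(a, dtype=float)
    w[iu] = w_u
    w = w + w.T

    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    excluded_zero = {p for p, m in zip(pairs, zero_mask) if m}
    excluded_sd = {p for p, m in zip(pairs, sd_mask) if m}
    return ReconciledSC(
        weights=ConnectivityMatrix(w, list(run1.node_ids), "count"),
        excluded_zero=excluded_zero,
        excluded_sd=excluded_sd,
        sparsity=sparsity(w),
        sigma_d=sigma_d,
        metadata={"sd_rule": "3*sigma_d over both-nonzero edges", "combine": "sum"},
    )


def group_average(matrices: list) -> ConnectivityMatrix:
    """Elementwise arithmetic mean of connectomes, zeros included."""
    if not matrices:
        raise ValueError("group_average requires at least one matrix")
    arrs = [m.values for m in matrices]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("matrices differ in shape")
    mean = np.mean(arrs, axis=0)
    return ConnectivityMatrix(mean, list(matrices[0].node_ids), matrices[0].kind)


def threshold_top_fraction(matrix: ConnectivityMatrix, fraction: float = 0.30) -> ConnectivityMatrix:
    """Keep the ceil(fraction * n_pairs) strongest upper-triangle edges.

    Ties at the cutoff are broken by keeping lower (i, j) lexicographic pairs
    first, which makes permutation tests reproducible.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = matrix.n_nodes
    iu = _upper(n)
    w = matrix.values[iu]
    m = int(np.ceil(fraction * w.size))
    # stable sort on (-weight, i, j): lexicographic pairs win ties
    order = np.lexsort((iu[1], iu[0], -w))
    keep_idx = order[:m]
    out_u = np.zeros_like(w)
    out_u[keep_idx] = w[keep_idx]
    out = np.zeros_like(matrix.values)
    out[iu] = out_u
    out = out + out.T
    return ConnectivityMatrix(out, list(matrix.node_ids), matrix.kind)
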