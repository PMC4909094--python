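"""Network-based statistics on functional connectivity.

Edgewise two-sample t-tests (pooled variance, direction B > A positive) on
the absolute correlation values, suprathreshold connected-component
extraction, and family-wise-error-corrected component p-values from the
maximal component size (edge count) under group-label permutation, with the
(b + 1)/(m + 1) estimator so p is never zero.

The single-edge t threshold is deliberately high (t >= 5 by default): NBS
inference is over component extent, and low thresholds make the component
null distribution unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import ConnectivityMatrix

__all__ = ["NBSResult", "edgewise_tstats", "suprathreshold_components",
           "nbs_test", "subnetwork_hubs", "subnetwork_consistency"]


@dataclass
class NBSResult:
    t: np.ndarray
    threshold: float
    components: list                # each: set of (i, j) edges, i < j
    sizes: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int
    null_max_size: np.ndarray = field(default=None, repr=False)


def _stack(group, use_absolute: bool):
    mats = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
            for m in group]
    n = mats[0].shape[0]
    iu = np.triu_indices(n, 1)
    X = np.stack([np.abs(m[iu]) if use_absolute else m[iu] for m in mats])
    return X, n, iu


def _tstats(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per edge column; B (label 1) minus A."""
    a, b = X[labels == 0], X[labels == 1]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(ma)
    ok = denom > 0
    t[ok] = (mb - ma)[ok] / denom[ok]
    return t


def edgewise_tstats(group_a, group_b, use_absolute: bool = True) -> np.ndarray:
    """N x N matrix of pooled two-sample t statistics, direction B > A."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    Xa, n, iu = _stack(group_a, use_absolute)
    Xb, nb_n, _ = _stack(group_b, use_absolute)
    if nb_n != n:
        raise ValueError("group matrices differ in shape")
    X = np.vstack([Xa, Xb])
    labels = np.r_[np.zeros(Xa.shape[0], int), np.ones(Xb.shape[0], int)]
    t_u = _tstats(X, labels)
    zero_var = np.count_nonzero(
        (Xa.var(axis=0) == 0) & (Xb.var(axis=0) == 0))
    if zero_var:
        warnings.warn(f"{zero_var} edges had zero variance in both groups; t set to 0")
    t = np.zeros((n, n))
    t[iu] = t_u
    return t + t.T


def suprathreshold_components(t: np.ndarray, threshold: float) -> list:
    """Connected components of the graph of edges with t >= threshold.

    Returns a list of edge sets; component size is the edge count.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = t.shape[0]
    mask = np.triu(t >= threshold, 1)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return []
    adj = csr_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    ncomp, labels = connected_components(adj + adj.T, directed=False)
    comps = {}
    for i, j in zip(ii, jj):
        comps.setdefault(labels[i], set()).add((int(i), int(j)))
    return sorted(comps.values(), key=len, reverse=True)


def _max_component_sizes(t_u: np.ndarray, iu, n: int, threshold: float) -> int:
    mask = t_u >= threshold
    k = int(mask.sum())
    if k == 0:
        return 0
    if k == 1:
        return 1
    ii, jj = iu[0][mask], iu[1][mask]
    adj = csr_matrix((np.ones(k), (ii, jj)), shape=(n, n))
    ncomp, labels = connected_components(adj + adj.T, directed=False)
    return int(np.bincount(labels[ii], minlength=ncomp).max())


def nbs_test(group_a, group_b, threshold: float = 5.0, n_perm: int = 10000,
             seed: int = 0, use_absolute: bool = True) -> NBSResult:
    """NBS with FWE correction by maximal null component size (B > A)."""
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p-values are coarse")
    Xa, n, iu = _stack(group_a, use_absolute)
    Xb, _, _ = _stack(group_b, use_absolute)
    X = np.vstack([Xa, Xb])
    na = Xa.shape[0]
    labels = np.r_[np.zeros(na, int), np.ones(Xb.shape[0], int)]
    t_u = _tstats(X, labels)
    t = np.zeros((n, n))
    t[iu] = t_u
    t = t + t.T
    comps = suprathreshold_components(t, threshold)
    sizes = np.array([len(c) for c in comps], dtype=int)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        null_max[b] = _max_component_sizes(_tstats(X, rng.permutation(labels)), iu, n, threshold)
    p = np.array([(np.count_nonzero(null_max >= s) + 1.0) / (n_perm + 1.0) for s in sizes])
    return NBSResult(t=t, threshold=threshold, components=comps, sizes=sizes,
                     p=p, n_perm=n_perm, seed=seed, null_max_size=null_max)


def subnetwork_consistency(patient_fcs, control_mean_fc, component: set,
                           use_absolute: bool = True) -> np.ndarray:
    """Per-subject fraction of component edges exceeding the control mean.

    Generic per-subject validation of a group-level subnetwork: for each
    patient, the fraction of the component's edges whose (absolute) FC is
    above the control-group mean at that edge.
    """
    if not component:
        raise ValueError("empty component")
    cm = control_mean_fc.values if isinstance(control_mean_fc, ConnectivityMatrix) \
        else np.asarray(control_mean_fc, float)
    ii = np.array([e[0] for e in component])
    jj = np.array([e[1] for e in component])
    ref = np.abs(cm[ii, jj]) if use_absolute else cm[ii, jj]
    out = []
    for fc in patient_fcs:
        v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
        x = np.abs(v[ii, jj]) if use_absolute else v[ii, jj]
        out.append(float(np.mean(x > ref)))
    return np.asarray(out)


def subnetwork_hubs(component: set, degree_threshold: int = 5) -> list:
    """Nodes whose within-component degree is >= the threshold."""
    if not component:
        raise ValueError("empty component")
    deg = {}
    for i, j in component:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    return sorted(v for v, d in deg.items() if d >= degree_threshold)
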