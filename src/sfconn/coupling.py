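"""Structure-function coupling statistics.

Edgewise Pearson correlations of functional connectivity against structural
metrics on group-averaged connectomes, partial correlations controlling for
Euclidean distance, bidirectional stepwise multi-parametric regression, and
group-difference permutation tests on correlations and regression slopes,
stratified over whole-brain / NBS / rich-club / feeder / local edge sets.

Conventions: all statistics are computed over upper-triangle edges selected
by a boolean mask; masks always exclude non-finite metric values (e.g.
disconnected pairs carry infinite path length, non-positive counts carry NaN
log). Group comparisons use the intersection of both groups' validity masks
so a difference in r is well defined. Slopes are reported on standardised
predictors by default (slope = r * sd(FC)), so scale differences between
groups do not masquerade as coupling differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import linregress, pearsonr

from .io import ConnectivityMatrix
from .sc import group_average

__all__ = ["edgewise_correlation", "partial_correlation", "stepwise_regression",
           "permutation_group_difference", "stratified_report", "valid_mask",
           "EdgeMask", "standard_metric_fns"]


def standard_metric_fns(coords=None, coupling: float = None, si_variant: str = "no_return") -> dict:
    """Metric-name -> function-of-averaged-SC mapping for the standard set.

    Each function maps an averaged weight matrix to an edgewise metric
    matrix (NaN/inf marking invalid edges): log streamline count, weighted
    path length, search information (symmetrised), path transitivity, and —
    when coords / coupling are supplied — Euclidean distance and analytic FC.
    """
    from . import metrics as mt

    def _paths(W):
        return mt.shortest_paths(mt.edge_lengths(W))

    def _si(W):
        pl, paths = _paths(W)
        si = mt.search_information(W, paths, variant=si_variant)
        return (si + si.T) / 2.0

    fns = {
        "logcount": lambda W: np.where(W > 0, np.log(np.where(W > 0, W, 1.0)), np.nan),
        "pl": lambda W: _paths(W)[0],
        "pt": lambda W: mt.path_transitivity(W, _paths(W)[1]),
        "si": _si,
    }
    if coupling is not None:
        fns["fca"] = lambda W: mt.fca(W, coupling)
    if coords is not None:
        ed = mt.euclidean_distance(coords)
        fns["ed"] = lambda W: ed
    return fns


@dataclass
class EdgeMask:
    mask: np.ndarray                # N x N boolean, symmetric
    provenance: str = "whole_brain"


def _vals(m):
    return m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)


def valid_mask(metric) -> np.ndarray:
    """Edges where the metric is finite (excludes the diagonal)."""
    v = _vals(metric)
    ok = np.isfinite(v)
    np.fill_diagonal(ok, False)
    return ok


def _masked_pairs(metric, fc, mask):
    v, f = _vals(metric), _vals(fc)
    iu = np.triu_indices(v.shape[0], 1)
    sel = (mask & valid_mask(v))[iu] if mask is not None else valid_mask(v)[iu]
    return v[iu][sel], f[iu][sel]


def edgewise_correlation(metric, fc, mask=None) -> tuple:
    """Pearson r plus OLS slope/intercept of FC on the metric; returns
    (r, slope, intercept, n_edges)."""
    x, y = _masked_pairs(metric, fc, mask)
    if x.size <= 2:
        raise ValueError(f"need more than 2 edges, got {x.size}")
    res = linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept), int(x.size)


def partial_correlation(metric, fc, control, mask=None) -> float:
    """Correlation of FC and metric residuals after regressing out a control.

    A constant control reduces to the plain correlation; a control identical
    to the metric leaves zero residual variance and raises.
    """
    joint = valid_mask(metric) & valid_mask(control)
    if mask is not None:
        joint &= mask
    x, y = _masked_pairs(metric, fc, joint)
    c, _ = _masked_pairs(control, fc, joint)
    if x.size <= 2:
        raise ValueError(f"need more than 2 edges, got {x.size}")

    def resid(v):
        if np.std(c) == 0:
            return v - v.mean()
        design = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = resid(x), resid(y)
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)):
        raise ValueError("metric has no residual variance after removing the control")
    return float(pearsonr(rx, ry)[0])


def stepwise_regression(predictors: dict, fc, mask=None,
                        entry_p: float = 0.05, removal_p: float = 0.10) -> dict:
    """Bidirectional stepwise OLS of FC on standardised structural predictors.

    Returns the selected predictor set with coefficients and multiple R, plus
    the fixed full model including every predictor ("combined" model).
    Collinear predictors are dropped with a warning.
    """
    fcv = _vals(fc)
    iu = np.triu_indices(fcv.shape[0], 1)
    cols = {}
    sel_mask = np.ones(iu[0].size, bool)
    for name, m in predictors.items():
        v = _vals(m)
        sel_mask &= valid_mask(v)[iu]
    if mask is not None:
        sel_mask &= mask[iu]
    y = fcv[iu][sel_mask]
    for name, m in predictors.items():
        col = _vals(m)[iu][sel_mask]
        sd = col.std()
        if sd == 0:
            warnings.warn(f"predictor {name!r} is constant on the mask; dropped")
            continue
        cols[name] = (col - col.mean()) / sd
    # drop exactly collinear predictors
    names = list(cols)
    X_all = np.column_stack([cols[n] for n in names]) if names else np.empty((y.size, 0))
    keep = []
    for k, name in enumerate(names):
        trial = keep + [k]
        if np.linalg.matrix_rank(X_all[:, trial]) == len(trial):
            keep.append(k)
        else:
            warnings.warn(f"predictor {name!r} collinear with earlier ones; dropped")
    names = [names[k] for k in keep]

    included: list = []
    changed = True
    while changed:
        changed = False
        # forward step: best candidate below entry_p
        best, best_p = None, entry_p
        for cand in names:
            if cand in included:
                continue
            X = sm.add_constant(np.column_stack([cols[n] for n in included + [cand]]))
            pval = sm.OLS(y, X).fit().pvalues[-1]
            if pval < best_p:
                best, best_p = cand, pval
        if best is not None:
            included.append(best)
            changed = True
        # backward step: worst included above removal_p
        if included:
            X = sm.add_constant(np.column_stack([cols[n] for n in included]))
            pv = sm.OLS(y, X).fit().pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > removal_p:
                included.pop(worst)
                changed = True

    def fit(sel):
        if not sel:
            model = sm.OLS(y, np.ones((y.size, 1))).fit()
            return {"predictors": [], "coef": {}, "R": 0.0, "r2": 0.0, "model": model}
        X = sm.add_constant(np.column_stack([cols[n] for n in sel]))
        model = sm.OLS(y, X).fit()
        return {"predictors": list(sel),
                "coef": dict(zip(sel, model.params[1:])),
                "R": float(np.sqrt(max(model.rsquared, 0.0))),
                "r2": float(model.rsquared), "model": model}

    out = fit(included)
    out["full_model"] = fit(names)
    out["n_edges"] = int(y.size)
    return out


def _group_stat(avg_sc_like, avg_fc, metric_fn, statistic, mask):
    metric = metric_fn(avg_sc_like)
    m = valid_mask(metric) & mask if mask is not None else valid_mask(metric)
    r, slope, _, n = edgewise_correlation(metric, avg_fc, m)
    if statistic == "r":
        return r
    x, y = _masked_pairs(metric, avg_fc, m)
    return r * y.std()            # slope on the standardised predictor


def permutation_group_difference(sc_a, fc_a, sc_b, fc_b, metric_fn,
                                 statistic: str = "r", mask=None, mask_fn=None,
                                 n_perm: int = 10000, seed: int = 0) -> dict:
    """Two-sided permutation test on the group difference of r or slope.

    The statistic is computed on group-averaged SC and FC; the null is built
    by relabeling subjects and re-averaging. A fixed ``mask`` (e.g. from an
    observed NBS run) is held constant across permutations; a ``mask_fn``
    (signature mask_fn(avg_sc_a, avg_sc_b) -> bool matrix, e.g. rich-club
    strata) is recomputed per permutation. Failed permutations are discarded
    and counted.
    """
    if statistic not in ("r", "slope"):
        raise ValueError("statistic must be 'r' or 'slope'")
    sc_a = [_vals(m) for m in sc_a]
    sc_b = [_vals(m) for m in sc_b]
    fc_a = [_vals(m) for m in fc_a]
    fc_b = [_vals(m) for m in fc_b]

    def stat_diff(ia, ib, sc_all, fc_all):
        avg = lambda idx, mats: np.mean([mats[i] for i in idx], axis=0)
        sa, sb = avg(ia, sc_all), avg(ib, sc_all)
        fa, fb = avg(ia, fc_all), avg(ib, fc_all)
        m = mask
        if mask_fn is not None:
            mf = mask_fn(sa, sb)
            m = mf if m is None else (m & mf)
        ma = metric_fn(sa)
        mb = metric_fn(sb)
        joint = valid_mask(ma) & valid_mask(mb)
        m = joint if m is None else (m & joint)
        return (_group_stat(sb, fb, metric_fn, statistic, m)
                - _group_stat(sa, fa, metric_fn, statistic, m))

    sc_all = sc_a + sc_b
    fc_all = fc_a + fc_b
    na, ntot = len(sc_a), len(sc_all)
    obs = stat_diff(list(range(na)), list(range(na, ntot)), sc_all, fc_all)
    rng = np.random.default_rng(seed)
    exceed = 0
    failed = 0
    for _ in range(n_perm):
        perm = rng.permutation(ntot)
        try:
            null = stat_diff(perm[:na].tolist(), perm[na:].tolist(), sc_all, fc_all)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        if abs(null) >= abs(obs):
            exceed += 1
    done = n_perm - failed
    if failed:
        warnings.warn(f"{failed} permutations discarded")
    return {"observed": obs, "p": (exceed + 1.0) / (done + 1.0),
            "n_perm": done, "seed": seed, "statistic": statistic}


def stratified_report(sc_a, fc_a, sc_b, fc_b, metric_fns: dict, strata: dict,
                      n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Metric x stratum x group grid of r and slope with permutation p.

    ``metric_fns`` maps metric name -> function of the averaged SC matrix;
    ``strata`` maps stratum name -> fixed boolean edge mask (N x N). Strata
    with fewer than 3 valid edges are reported as missing.
    """
    avg_a = np.mean([_vals(m) for m in sc_a], axis=0)
    avg_b = np.mean([_vals(m) for m in sc_b], axis=0)
    fca_avg = np.mean([_vals(m) for m in fc_a], axis=0)
    fcb_avg = np.mean([_vals(m) for m in fc_b], axis=0)
    rows = []
    for mname, fn in metric_fns.items():
        met_a, met_b = fn(avg_a), fn(avg_b)
        joint = valid_mask(met_a) & valid_mask(met_b)
        for sname, smask in strata.items():
            m = joint if smask is None else (joint & smask)
            iu = np.triu_indices(m.shape[0], 1)
            n_edges = int(m[iu].sum())
            row = {"metric": mname, "stratum": sname, "n_edges": n_edges}
            if n_edges < 3:
                rows.append(row)
                continue
            for gname, met, fc in (("A", met_a, fca_avg), ("B", met_b, fcb_avg)):
                r, slope, _, _ = edgewise_correlation(met, fc, m)
                row[f"r_{gname}"] = r
                row[f"slope_{gname}"] = slope
            perm = permutation_group_difference(
                sc_a, fc_a, sc_b, fc_b, fn, statistic="r", mask=smask,
                n_perm=n_perm, seed=seed)
            row["delta_r"] = perm["observed"]
            row["p_delta_r"] = perm["p"]
            rows.append(row)
    return pd.DataFrame(rows)
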