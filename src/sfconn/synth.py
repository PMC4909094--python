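"""Synthetic cohort generator for structure-function coupling analyses.

Emulates the statistical structure the pipeline assumes, so every stage is
testable without MRI data:

* geometry — two mirrored hemispheric shells of region centres (mm);
* structure — latent edge weights decaying exponentially with Euclidean
  distance, a bilateral high-degree/high-weight core (rich club), homotopic
  weight bonus, edge presence sampled to a target sparsity, and two
  independent Poisson "tractography runs" around the latent means with a
  configurable discordant fraction to exercise the reconciliation filter;
* BOLD — stationary Gaussian series whose covariance is the analytic-FC
  covariance (I - c W)^-1 plus diagonal measurement noise, optionally AR(1)
  filtered so the wavelet stage sees non-flat spectra, with motion/CSF/WM/
  global confound channels linearly mixed in;
* patient effects — a connected hypercorrelated FC subnetwork (shared latent
  signals on a recorded ground-truth edge set), weak off-path branch edges
  that raise search information, and optionally a stronger structure-function
  coupling for the patient group.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ConnectivityMatrix
from .metrics import SpectralConditionError, _normalise_w, euclidean_distance

__all__ = ["PatientEffect", "CohortSpec", "SyntheticSubject", "generate_geometry",
           "generate_structural_runs", "generate_bold", "inject_patient_effects",
           "generate_cohort", "write_cohort"]


@dataclass
class PatientEffect:
    """Group-level alterations injected into the patient cohort."""

    fc_boost_edges: int = 30        # size of the hypercorrelated subnetwork
    fc_boost_r: float = 0.4         # target correlation increment on those edges
    si_branch_edges: int = 20       # weak branch edges added to raise SI
    coupling_increase: float = 0.0  # additive increment to the FCA coupling c


@dataclass
class CohortSpec:
    """Study conditions for a synthetic controls/patients cohort.

    Defaults mirror the emulated acquisition: 0.45 structural sparsity,
    TR 3.6 s, 350 BOLD frames, coupling c = 0.32; 13 controls vs 7 patients.
    """

    n_nodes: int = 128
    n_controls: int = 13
    n_patients: int = 7
    sparsity_target: float = 0.45
    distance_decay: float = 0.05    # 1/mm
    hub_fraction: float = 0.125
    hub_boost: float = 2.0
    homotopic_boost: float = 1.5
    coupling_c: float = 0.32
    ts_length: int = 350
    tr: float = 3.6
    noise_sd: float = 0.5
    ar_coef: float = 0.3
    mean_count: float = 30.0
    min_mean_count: float = 4.0     # floor on latent run means (limits Poisson zeros)
    discordant_fraction: float = 0.02
    patient_effect: PatientEffect = field(default_factory=PatientEffect)
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 8:
            raise ValueError(f"need n_nodes >= 8, got {self.n_nodes}")
        if not 0 < self.sparsity_target <= 1:
            raise ValueError("sparsity_target must be in (0, 1]")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    run1: ConnectivityMatrix
    run2: ConnectivityMatrix
    coords: pd.DataFrame
    bold: np.ndarray                # T x N
    confounds: np.ndarray           # T x 9
    latent: np.ndarray = None       # latent mean weight matrix (generator internal)
    tr: float = 3.6


def generate_geometry(n_nodes: int, seed: int = 0) -> pd.DataFrame:
    """Region centres on two mirrored hemispheric shells.

    Left-hemisphere points are sampled on a shell around (-35, 0, 0) mm with
    radius 20-34 mm (so x < 0); the right hemisphere is the exact mirror,
    giving homotopic pairs. Nodes split evenly, left first.
    """
    if n_nodes < 8:
        raise ValueError(f"need n_nodes >= 8, got {n_nodes}")
    rng = np.random.default_rng(seed)
    n_left = (n_nodes + 1) // 2
    u = rng.standard_normal((n_left, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(20.0, 34.0, n_left)
    left = u * r[:, None] + np.array([-35.0, 0.0, 0.0])
    right = left[: n_nodes - n_left] * np.array([-1.0, 1.0, 1.0])
    rows = []
    for i, (x, y, z) in enumerate(left):
        rows.append((i, f"L{i:03d}", "L", x, y, z))
    for i, (x, y, z) in enumerate(right):
        rows.append((n_left + i, f"R{i:03d}", "R", x, y, z))
    return pd.DataFrame(rows, columns=["node_id", "label", "hemisphere", "x", "y", "z"])


def _core_nodes(spec: CohortSpec) -> np.ndarray:
    """Bilateral hub core: the first hub_fraction of homotopic pairs."""
    n_left = (spec.n_nodes + 1) // 2
    n_core = max(2, int(round(spec.hub_fraction * spec.n_nodes)))
    per_hemi = n_core // 2
    return np.r_[np.arange(per_hemi), n_left + np.arange(n_core - per_hemi)]


def _latent_weights(spec: CohortSpec, coords: pd.DataFrame):
    """Latent mean weight matrix and the selected edge set (upper triangle)."""
    n = spec.n_nodes
    ed = euclidean_distance(coords)
    lam = np.exp(-spec.distance_decay * ed)
    core = _core_nodes(spec)
    core_mask = np.zeros(n, bool)
    core_mask[core] = True
    lam[np.ix_(core_mask, core_mask)] *= spec.hub_boost
    n_left = (n + 1) // 2
    homot = np.arange(n - n_left)
    lam[homot, n_left + homot] *= spec.homotopic_boost
    lam[n_left + homot, homot] *= spec.homotopic_boost
    np.fill_diagonal(lam, 0.0)
    iu = np.triu_indices(n, 1)
    lam_u = lam[iu]
    m = int(round(spec.sparsity_target * lam_u.size))
    if m > lam_u.size:
        raise ValueError("sparsity_target requests more edges than node pairs")
    rng = np.random.default_rng((spec.seed, 101))
    chosen = rng.choice(lam_u.size, size=m, replace=False, p=lam_u / lam_u.sum())
    mu_u = np.zeros_like(lam_u)
    sel = lam_u[chosen]
    mu_u[chosen] = spec.min_mean_count + (spec.mean_count - spec.min_mean_count) * sel / sel.mean()
    mu = np.zeros((n, n))
    mu[iu] = mu_u
    return mu + mu.T, chosen, iu


def generate_structural_runs(spec: CohortSpec, subject_index: int,
                             coords: pd.DataFrame = None) -> SyntheticSubject:
    """One subject's pair of Poisson tractography runs around the latent means."""
    if coords is None:
        coords = generate_geometry(spec.n_nodes, spec.seed)
    mu, chosen, iu = _latent_weights(spec, coords)
    rng = np.random.default_rng((spec.seed, 7, subject_index))
    mu_u = mu[iu]
    r1 = rng.poisson(mu_u).astype(float)
    r2 = rng.poisson(mu_u).astype(float)
    n_disc = int(round(spec.discordant_fraction * chosen.size))
    if n_disc:
        disc = rng.choice(chosen, size=n_disc, replace=False)
        which = rng.integers(0, 2, size=n_disc)
        r1[disc[which == 0]] = 0.0
        r2[disc[which == 1]] = 0.0
        # keep the other run's count positive so discordance is visible
        r1[disc[which == 1]] = np.maximum(r1[disc[which == 1]], 1.0)
        r2[disc[which == 0]] = np.maximum(r2[disc[which == 0]], 1.0)
    n = spec.n_nodes

    def as_mat(u):
        m = np.zeros((n, n))
        m[iu] = u
        return ConnectivityMatrix(m + m.T, list(range(n)), "count")

    bold, confounds = generate_bold(
        mu, spec.coupling_c, spec.ts_length, spec.noise_sd,
        seed=(spec.seed, 13, subject_index), ar_coef=spec.ar_coef, with_confounds=True)
    return SyntheticSubject(
        subject_id=f"sub-{subject_index:03d}", group="control",
        run1=as_mat(r1), run2=as_mat(r2), coords=coords,
        bold=bold, confounds=confounds, latent=mu, tr=spec.tr)


def generate_bold(sc, coupling_c: float, ts_length: int, noise_sd: float,
                  seed=0, ar_coef: float = 0.0, with_confounds: bool = False):
    """Stationary Gaussian BOLD with the analytic-FC covariance plus noise.

    Covariance is (I - c W~)^-1 + noise_sd^2 I with W~ the largest-eigenvalue
    normalisation of sc. Raises SpectralConditionError when c is inadmissible.
    An AR(1) filter (ar_coef) adds temporal autocorrelation without changing
    zero-lag cross-correlations. When with_confounds is set, nine confound
    channels (6 motion random walks, CSF, WM, global) are generated and
    linearly mixed into the data.
    """
    W = sc.values if isinstance(sc, ConnectivityMatrix) else np.asarray(sc, float)
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    if coupling_c == 0 or not (W > 0).any():
        cov = np.eye(n)
    else:
        Wn, c_max = _normalise_w(W)
        if coupling_c >= c_max:
            eig = np.linalg.eigvalsh(coupling_c * Wn)
            bad = eig[np.argmax(np.abs(eig))]
            raise SpectralConditionError(
                f"covariance not positive definite: coupling eigenvalue {bad:.4f} "
                f"outside (-1, 1); admissible c < {c_max:.4f}")
        cov = np.linalg.inv(np.eye(n) - coupling_c * Wn)
    cov = cov + noise_sd ** 2 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((ts_length, n)) @ chol.T
    if ar_coef:
        from scipy.signal import lfilter
        x = lfilter([np.sqrt(1.0 - ar_coef ** 2)], [1.0, -ar_coef], x, axis=0)
    if not with_confounds:
        return x
    motion = np.cumsum(rng.normal(0.0, [0.02] * 3 + [4e-4] * 3, (ts_length, 6)), axis=0)
    csf_wm = rng.standard_normal((ts_length, 2))
    artifact = rng.standard_normal(ts_length)            # global nuisance component
    x = x + 0.3 * artifact[:, None]
    loadings = rng.normal(0.0, 0.1, (8, n))
    x = x + np.column_stack([motion, csf_wm]) @ loadings
    global_chan = x.mean(axis=1)
    confounds = np.column_stack([motion, csf_wm, global_chan])
    return x, confounds


def _connected_edge_set(n: int, n_edges: int, rng, max_degree: int = 3) -> list:
    """Grow a connected edge set of the requested size with capped degrees.

    The degree cap keeps the per-edge correlation boost achievable: a node
    shared by many boosted edges accumulates latent variance that dilutes
    each edge's correlation.
    """
    if n_edges > n * max_degree // 2:
        raise ValueError("not enough node capacity for the requested edge set")
    deg = np.zeros(n, int)
    start = int(rng.integers(n))
    nodes = [start]
    in_set = {start}
    edges = set()
    while len(edges) < n_edges:
        open_nodes = [u for u in nodes if deg[u] < max_degree]
        if not open_nodes:
            raise ValueError("degree cap exhausted before reaching the edge count")
        u = int(rng.choice(open_nodes))
        order = rng.permutation(n)
        added = False
        for v in order:
            v = int(v)
            e = (min(u, v), max(u, v))
            if v == u or deg[v] >= max_degree or e in edges:
                continue
            edges.add(e)
            deg[u] += 1
            deg[v] += 1
            if v not in in_set:
                in_set.add(v)
                nodes.append(v)
            added = True
            break
        if not added:
            raise ValueError("not enough available pairs for the requested edge set")
    return sorted(edges)


def _boost_amplitudes(edges: list, n: int, target_r: float) -> np.ndarray:
    """Per-edge latent amplitudes (variance units) realising the target
    correlation increment on every boosted edge.

    Solves a_e^2 = r * sqrt((1 + S_i)(1 + S_j)) with S_i the summed latent
    variance at node i, by damped fixed-point iteration; amplitudes are
    capped so infeasible corners degrade gracefully instead of diverging.
    """
    a2 = np.full(len(edges), target_r)
    for _ in range(200):
        S = np.zeros(n)
        for e, (i, j) in enumerate(edges):
            S[i] += a2[e]
            S[j] += a2[e]
        new = np.array([target_r * np.sqrt((1 + S[i]) * (1 + S[j])) for i, j in edges])
        new = np.minimum(new, 16.0)
        if np.max(np.abs(new - a2)) < 1e-10:
            a2 = new
            break
        a2 = 0.5 * a2 + 0.5 * new
    return a2


def inject_patient_effects(subject: SyntheticSubject, effect: PatientEffect, seed=0,
                           fc_edges: list = None, si_edges: list = None) -> tuple:
    """Apply patient-group alterations; returns (subject, ground_truth).

    ground_truth = {"fc_edges": [...], "si_edges": [...]}. Zero-magnitude
    effects return the subject unchanged. The FC boost adds one shared latent
    series per ground-truth edge to the two incident regions' BOLD; branch
    edges are added to both structural runs with a small equal count so they
    survive reconciliation yet barely perturb shortest paths.
    """
    rng = np.random.default_rng(seed)
    truth = {"fc_edges": list(fc_edges or []), "si_edges": list(si_edges or [])}
    if effect.fc_boost_edges == 0 and effect.si_branch_edges == 0:
        return subject, truth
    n = subject.run1.n_nodes
    r1 = subject.run1.values.copy()
    r2 = subject.run2.values.copy()
    bold = subject.bold.copy()

    if effect.si_branch_edges > 0:
        if si_edges is None:
            absent = np.argwhere(np.triu((r1 == 0) & (r2 == 0), 1))
            if absent.shape[0] < effect.si_branch_edges:
                raise ValueError("not enough absent edges for si_branch_edges")
            pick = rng.choice(absent.shape[0], effect.si_branch_edges, replace=False)
            si_edges = [tuple(map(int, absent[p])) for p in pick]
            truth["si_edges"] = si_edges
        for i, j in si_edges:
            r1[i, j] = r1[j, i] = r2[i, j] = r2[j, i] = 2.0

    if effect.fc_boost_edges > 0:
        if fc_edges is None:
            fc_edges = _connected_edge_set(n, effect.fc_boost_edges, rng)
            truth["fc_edges"] = fc_edges
        sd = bold.std(axis=0)
        a2 = _boost_amplitudes(fc_edges, n, effect.fc_boost_r)
        for (i, j), amp in zip(fc_edges, a2):
            z = rng.standard_normal(bold.shape[0])
            bold[:, i] += np.sqrt(amp) * sd[i] * z
            bold[:, j] += np.sqrt(amp) * sd[j] * z

    out = replace(subject,
                  run1=ConnectivityMatrix(r1, list(subject.run1.node_ids), "count"),
                  run2=ConnectivityMatrix(r2, list(subject.run2.node_ids), "count"),
                  bold=bold, group="patient")
    return out, truth


def generate_cohort(spec: CohortSpec) -> dict:
    """Controls and patients sharing one geometry; ground truth recorded.

    Patient structural runs and BOLD are generated like controls (with the
    coupling incremented by patient_effect.coupling_increase), then the FC
    and SI effects are injected on cohort-level ground-truth edge sets.
    """
    coords = generate_geometry(spec.n_nodes, spec.seed)
    controls = [generate_structural_runs(spec, i, coords) for i in range(spec.n_controls)]
    eff = spec.patient_effect
    pat_spec = replace(spec, coupling_c=spec.coupling_c + eff.coupling_increase)
    truth_rng = np.random.default_rng((spec.seed, 23))
    fc_edges = si_edges = None
    patients = []
    truth = {"fc_edges": [], "si_edges": []}
    for i in range(spec.n_patients):
        base = generate_structural_runs(pat_spec, spec.n_controls + i, coords)
        subj, t = inject_patient_effects(
            base, eff, seed=(spec.seed, 29, i), fc_edges=fc_edges, si_edges=si_edges)
        if fc_edges is None and (t["fc_edges"] or t["si_edges"]):
            # first patient fixes the cohort-level ground truth
            fc_edges, si_edges = t["fc_edges"] or None, t["si_edges"] or None
            truth = {"fc_edges": t["fc_edges"], "si_edges": t["si_edges"]}
        subj = replace(subj, subject_id=f"pat-{i:03d}")
        patients.append(subj)
    return {"spec": spec, "coords": coords, "controls": controls,
            "patients": patients, "truth": truth}


def write_cohort(cohort: dict, outdir) -> None:
    """Write runs and BOLD as TSV, manifest as JSON, truth edges as TSV."""
    import json
    from pathlib import Path

    from .io import save_matrix, save_node_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_node_table(cohort["coords"], outdir / "nodes.tsv")
    manifest = {"subjects": [], "seed": cohort["spec"].seed}
    for subj in cohort["controls"] + cohort["patients"]:
        sdir = outdir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        save_matrix(subj.run1, sdir / "run1.tsv")
        save_matrix(subj.run2, sdir / "run2.tsv")
        np.savetxt(sdir / "bold.tsv", subj.bold, delimiter="\t")
        np.savetxt(sdir / "confounds.tsv", subj.confounds, delimiter="\t")
        manifest["subjects"].append(
            {"id": subj.subject_id, "group": subj.group, "dir": subj.subject_id})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    truth = cohort["truth"]
    with open(outdir / "truth_fc_edges.tsv", "w") as fh:
        fh.write("i\tj\n")
        for i, j in truth["fc_edges"]:
            fh.write(f"{i}\t{j}\n")
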