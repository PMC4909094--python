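# Methods

This note documents the models implemented in `sfconn`, the parameter
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical decisions that affect results.

## Structural connectome reconciliation

Two tractography runs per subject are merged into one count matrix. An edge
is excluded when (a) either run has zero streamlines, or (b) the absolute
run difference exceeds 3σ_d, where σ_d is the standard deviation of run
differences over the edges nonzero in both runs of that subject. σ_d is
computed on both-nonzero edges only: zero-in-one-run edges are already
removed by rule (a), and including their (large) differences would inflate
σ_d and blunt rule (b). Surviving weights are the **sum** of the two runs —
summing preserves count semantics, and every downstream use is either
scale-invariant (correlations, rich-club ratios, SI) or log-transformed.
Sparsity is the fraction of upper-triangle pairs with a nonzero weight.

Top-fraction thresholding keeps the ⌈f·N(N−1)/2⌉ strongest upper-triangle
edges; ties at the cutoff keep lexicographically smaller (i, j) pairs, so
repeated runs and permutation tests see identical matrices. For group
rich-club analysis each subject is thresholded at 30 % before averaging
(an average-then-threshold order is available as an option).

## Functional connectome

Nuisance regression is ordinary least squares of each regional series on an
intercept plus the confound columns (6 motion, CSF, WM and, by default, the
global mean); residuals are exactly orthogonal to the confounds and the
operation is idempotent. The wavelet stage uses an undecimated (shift
invariant) transform with the Daubechies least-asymmetric filter of length
8 and periodic boundary handling, keeping the scale-2 detail coefficients;
Pearson correlation between regional coefficient series gives FC. At
TR = 3.6 s scale 2 spans ≈ [1/(2³·TR), 1/(2²·TR)] = [0.035, 0.069] Hz.
Boundary coefficients are retained (trimming would discard ~14 frames of a
350-frame series); the band-selectivity of the result, not individual
coefficients, is the tested contract. Pearson correlation is invariant to
the transform's per-scale rescaling convention, so the choice of
normalisation does not affect FC. FD follows the Power convention
(rotations converted at a 50 mm head radius); DVARS is the RMS
frame-to-frame signal change over regions.

## Communication metrics

Edge lengths are inverse streamline counts; absent edges are infinite.
Shortest paths are computed by Dijkstra on the length matrix; among
equal-length paths the lexicographically smallest node sequence is stored,
by greedy descent on the distance field (at node u take the smallest
neighbour v with L(u,v) + d(v,t) = d(u,t), tolerance 1e-9 relative).
Degenerate ties are rare with continuous weights; the rule exists so that
permutation tests are exactly reproducible.

Search information: SI(s→t) = −log₂ of the probability that a random
walker emits the stored shortest path, with step probability
w(k, next)/S(k), where S(k) is the outgoing strength of node k. The default
walker cannot immediately backtrack (the edge just traversed is removed
from the denominator); a memoryless variant is available. SI is asymmetric
in its endpoints; the bundled metric matrix is the mean of the two
directions, one value per pair, for correlation against symmetric FC.

Path transitivity: PT(s,t) is the mean, over node pairs (u,v) of the
stored path, of the weighted matching index — the summed weight of edges to
shared neighbours divided by the total weight incident to u or v, the
direct u–v edge excluded from both. PT ∈ [0, 1]; 1 on uniform complete
graphs, 0 for an isolated dyad. Both SI and PT are validated against
brute-force oracles (an explicit Markov-chain state enumeration and a
neighbour-enumeration matching index) on hundreds of random graphs.

## Analytic functional connectivity and coupling

The linear model Cov = (I − cW̃)⁻¹ is the stationary covariance of a
first-order system with unit leak and coupling cW̃; FCA is its correlation
form. W̃ is W normalised by its largest eigenvalue, making c dimensionless
with admissible range (0, 1) for non-negative symmetric W — raw streamline
counts of order 10³ would otherwise make any fixed c meaningless. The
coupling is fitted by maximising the Pearson correlation between
upper-triangle FCA(W̃, c) and empirical FC over a grid (default step 0.01);
c = 0 is a degenerate boundary (identity FCA, zero predictor variance) and
is excluded.

A caveat established during validation: because Pearson correlation is
scale-invariant and FCA(c) ≈ cW̃ to first order, the fit objective
discriminates c only through higher-order path terms and is very flat
(1 − r < 10⁻³ across |Δc| ≈ 0.1 on 64-node connectomes). Recovery of a
known c is exact from noiseless FCA and accurate for edge noise small
relative to the FCA edge scale (which is ~0.01–0.02 at 64 nodes), but the
estimator is not robust to noise several times that scale. Fits against
empirical FC should therefore be read as "best projection onto the FCA
family", not as a sharply identified parameter.

## Rich club

φʷ(k) = W₍₎ₖ / Σ top-E₍₎ₖ ranked weights, with degrees computed on the
binarised (thresholded) matrix and the subgraph induced by nodes of degree
> k. Normalisation divides by the mean φʷ(k) of null networks built by
Maslov–Sneppen double-edge swaps (10 per edge) that preserve the degree
sequence exactly, with the observed weight multiset randomly reassigned to
the rewired edges. φʷ monotonicity in k is not asserted — it is not
guaranteed for the weighted variant. Cores at threshold k are nodes of
degree > k; edges are classified rich-club (core–core), feeder
(core–periphery) or local (periphery–periphery), a partition of all present
edges. Group differences in core size are tested by permuting subject
labels and rebuilding the averaged, thresholded connectome (two-sided,
(b+1)/(m+1) p-values). Default k range is ⌊0.3N⌋…⌊0.7N⌋, scaling the
customary 150–350 band at N = 512 to arbitrary parcellations.

## Network-based statistics

Edgewise two-sample pooled-variance t-statistics on |FC| (anticorrelations
count as connections), one-sided direction B > A; components of the t ≥ 5
suprathreshold graph are measured by edge count; the null distribution of
the maximal component size under subject-label permutation gives
family-wise corrected p-values with the (b+1)/(m+1) estimator, so p is
never 0 and never below 1/(m+1). Component extent (not intensity) is the
statistic. Zero-variance edges get t = 0 with a warning. The high default
threshold follows standard NBS practice: component inference is unstable
for low single-edge thresholds.

## Structure–function coupling statistics

All edgewise statistics are computed over upper-triangle masks that exclude
invalid entries (infinite PL/SI for disconnected pairs, NaN log-counts for
absent edges); group comparisons use the intersection of both groups'
validity masks so Δr is well defined. Slopes are reported on standardised
predictors (slope = r·sd(FC)) so scale differences between group metrics do
not masquerade as coupling differences; a raw-scale option exists.
Permutation tests relabel subjects, re-average SC and FC, recompute the
metric and the statistic, and use two-sided (b+1)/(m+1) p-values. A fixed
externally supplied mask (e.g. the observed NBS subnetwork) is held
constant across permutations — recomputing it would test a different
hypothesis — whereas data-dependent masks (rich-club strata) can be
recomputed per permutation via a mask function. Stepwise regression is
bidirectional with entry p = 0.05 and removal p = 0.10 (the conventional
defaults), on standardised predictors, with exactly collinear predictors
dropped; the fixed full model over all predictors is always reported
alongside the selected one.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- **Geometry**: region centres on two mirrored hemispheric shells (left
  shell centred at (−35, 0, 0) mm, radii 20–34 mm), giving exact homotopic
  pairs and strictly positive inter-node distances.
- **Structure**: latent weights decay exponentially with Euclidean
  distance (default 0.05 /mm — over the 20–120 mm distance range this gives
  a ~150-fold weight range, matching the strong distance dependence of
  streamline counts); a bilateral core of the first 12.5 % of homotopic
  pairs has core–core weights boosted ×2 (rich club); homotopic edges get a
  ×1.5 bonus. Edges are sampled without replacement with probability
  proportional to the latent weight until the target sparsity (default
  0.45) is met. Each run draws independent Poisson counts around the latent
  mean (floor 4, scale 30); the run-to-run Poisson choice is a simple
  stand-in for tractography run variability, which is not otherwise
  characterised. A configurable 2 % of present edges are made discordant
  (zeroed in one run) to exercise the reconciliation filter.
- **BOLD**: zero-mean Gaussian series with covariance (I − cW̃)⁻¹ + σ²I
  (defaults c = 0.32, σ = 0.5, T = 350, TR = 3.6 s), optionally AR(1)
  filtered (coefficient 0.3) so spectra are non-flat; zero-lag cross-
  correlations are unchanged by the filter. Nine confound channels
  (motion random walks, CSF, WM, global) are mixed into the data so the
  nuisance regression stage does real work.
- **Patient effects**: a connected hypercorrelated subnetwork (default 30
  edges, target correlation increment 0.4) realised by per-edge shared
  latent series whose amplitudes are solved by fixed-point iteration so the
  realised increment matches the target even when nodes carry several
  boosted edges (the effect subgraph caps node degree at 3 to keep the
  target feasible); weak branch edges (default 20, count 2 in both runs)
  that raise search information without moving shortest paths; and
  optionally an additive coupling increment for the patient group's BOLD.
  Ground-truth edge sets are recorded and shared across patients. The
  branch-edge SI effect is deliberately gentle (~10⁻²–10⁻³ bits at 64
  nodes: heavier edges would reverse the sign by creating shortcut
  routes), so it is resolvable in paired pre/post comparisons but not in
  unpaired group tests at desk-scale cohort sizes.

What the generator does **not** emulate: image-space artefacts (no
volumes, no tractography), spatial autocorrelation of BOLD noise,
physiological rhythms, heavy-tailed motion, inter-subject anatomical
variability beyond Poisson count noise, or negative structural FC
relationships. Passing tests therefore demonstrate correctness and
calibration of the analysis machinery under the stated model, not
robustness to every property of real MRI data.

## Problem sizes and defaults in the validation suite

The test suite and the acceptance script run at 64 nodes with 8-vs-8
cohorts, 200–1000 permutations and 200–500 rich-club nulls; these sizes
give stable statistics (the permutation machinery is exact for any size)
while keeping the full suite inside a desktop-scale run. The analysis code
itself is written for N up to 512 (matrices are dense; all-pairs paths are
the dominant cost, ~seconds at N = 512).

## Known limitations

- SI and PT are computed on the single stored (tie-broken) shortest path;
  degenerate alternatives are ignored by design.
- The coupling fit identifies c sharply only when FC noise is small
  relative to the FCA edge scale (see above).
- The weighted rich-club null (topology rewiring + weight shuffle) is one
  of several reasonable weighted nulls; strength-sequence-preserving nulls
  are not implemented.
- No covariate adjustment in NBS; no frame censoring in the FC pipeline.
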