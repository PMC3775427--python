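# Methods

This note documents the models, conventions and design choices behind
`netshift`: what each pipeline stage computes, which parameters matter,
what the synthetic data do and do not emulate, and where the design was
genuinely open.

## The comparison problem

Two weighted connectivity matrices over the same ordered ROI set — a
meta-analytic task coactivation matrix and a group resting-state
correlation matrix — live on different scales, so their raw weights are
not directly comparable. The pipeline therefore compares *binary graph
configurations at matched sparsity*: at each sparsity s both matrices are
binarized to exactly m = round(s·n(n−1)/2) edges (round half away from
zero), and all inference is about the resulting graphs. With n = 140
ROIs, s = 0.20 gives m = 1946 edges on 9730 node pairs. The sweep covers
s = 0.06…0.40 in steps of 0.01 (35 levels), the range in which large-scale
brain graphs are typically connected yet sparse enough to be non-trivial.

Weight ties at the threshold boundary are broken by lexicographic (i, j)
order. This is deliberate: it makes edge sets — and hence every
downstream permutation draw — bit-reproducible without a tiebreak RNG.
Ties are measure-zero for continuous weights, so the rule only matters
for degenerate inputs.

## Coactivation builder

Given a non-negative seed×target matrix V (row = one seed ROI's value at
every target ROI), the builder computes

  W = ½ (U + Uᵀ),  U = ln(1 + V / diag(V)) ,

i.e. row normalization by the seed's self-coactivation, a log(1+x)
de-skew, and symmetrization. Properties used as tests: the diagonal is
exactly ln 2; multiplying any row of V by a positive constant leaves W
unchanged (this is the point of the normalization — different seed
inquiries return different numbers of studies); increasing a raw pair
(i, j)/(j, i) never decreases W_ij.

Open choices, resolved as follows:

* **Log base** — natural log. Any base is a positive rescaling of any
  other, so edge *ranking*, and therefore every thresholded binary graph,
  is base-invariant; the choice is cosmetic and documented rather than
  configurable.
* **Sphere statistic** — the mean over in-sphere voxels (voxel center
  within the 10 mm radius, closed ball). Mean extraction is standard ROI
  practice and robust to single-voxel noise; `max` and `center` are
  available as options. Values absent from a thresholded map are read as
  zero, since a thresholded map carries no sub-threshold information.

## Resting-state builder

Per subject: (1) motion screen — a subject is excluded iff the maximum
absolute *translation* exceeds 3 mm (strictly greater; rotations are
logged, not thresholded, since the criterion is in mm); (2) OLS
regression of a T×23 nuisance design: 6 motion parameters, their
backward-difference derivatives (first row 0 — any constant offset is
absorbed by the intercept), 5 WM eigenvectors, 5 CSF eigenvectors, and an
intercept; rank deficiency falls back to the pseudoinverse with a logged
warning; (3) band-pass 0.01–0.1 Hz; (4) Kendall tau-b correlation matrix;
then group averaging via Fisher's z (atanh → mean → tanh), with the
diagonal set to 1 untransformed and |r| clipped at 1 − 1e-7 before atanh.

* **Filter** — the default is an ideal (hard-mask) filter on the real FFT
  with inclusive band edges, chosen because its pass/stop behaviour is
  exactly testable (a pass-band sinusoid survives bit-for-bit up to
  leakage; a stop-band bin is zeroed). A 4th-order zero-phase Butterworth
  (`filtfilt`) is provided for users who prefer a smooth transition band;
  it introduces edge transients the ideal mask does not.
* **Order** — nuisance regression before filtering (configurable). The
  regress-first order makes the group matrix exactly invariant to adding
  any multiple of a nuisance column to every ROI series, which is the
  invariance the test suite asserts (tolerance 1e-6; empirically the
  deviation is ~1e-15, limited only by rank flips of numerically tied
  samples, which continuous data make vanishingly unlikely).
* **Fisher z on tau** — atanh is conventionally paired with Pearson r,
  but it is applied to tau here because that is the averaging recipe this
  pipeline implements; it is monotone and invertible on (−1, 1), so group
  averaging remains well defined.
* **Tau variant** — tau-b (tie-corrected). Ties are rare in continuous
  BOLD-like data; the correction matters only for degenerate inputs.

## Graph metrics (from scratch)

Implemented directly rather than delegated, so the package's numbers have
a single, auditable definition; `networkx` serves as an independent
cross-check in the test suite only.

* **Global efficiency** — E = mean over ordered pairs i≠j of 1/d(i, j),
  with 1/∞ = 0 for disconnected pairs; distances by simultaneous BFS
  (boolean frontier matrix products), exact for unweighted graphs.
* **Clustering** — C_i = 2t_i/(k_i(k_i−1)), t_i = triangles through i
  (diag(A³)/2), C_i = 0 for degree < 2; the network value is the mean
  over all nodes.
* **Modularity** — Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j) over
  ordered pairs, diagonal included, computed on the full graph even when
  disconnected. Because A, k, m are integers for binary graphs, Q is
  evaluated as an exact integer numerator over (2m)² with one final
  division — bitwise-reproducible and directly comparable with brute
  force.
* **Louvain** — greedy local moves (first-improvement over a shuffled
  node order, gain tolerance 1e-12) followed by graph aggregation,
  iterated to a fixed point; best of 10 restarts by default, node order
  reshuffled per restart from the seed. The Q landscape is degenerate, so
  restarts stabilize the reported value; the returned q is always
  recomputed with the exact formula.
* **Random references** — uniform G(n, m) graphs (matching node and edge
  count), 1000 draws by default; a degree-preserving Maslov–Sneppen
  rewiring (10 attempted swaps per edge) is provided as an alternative
  since "random network" is ambiguous between the two conventions.
  G(n, m) is the default.

## Permutation inference

At each sparsity the two thresholded graphs share m edges in count but
not in identity. The null model: let D₁, D₂ be the private edge sets
(|D₁| = |D₂|); draw k = round-half-up(½|D₁|) edges from each side and
swap them. This preserves, exactly and per draw, both edge counts, the
intersection and the union — the conservation laws the suite asserts over
1000 random pairs. Exchanging equally sized subsets is the only reading
of "reassign 50% of the different edges" that preserves the
matched-sparsity contract; independent per-edge reassignment does not and
is rejected.

The p-value is the add-one estimator p = (1 + #{|null| ≥ |obs|})/(1 + N),
two-sided by default (one-sided available), so p > 0 always and the
smallest attainable p at N = 1000 is ≈ 0.001 — consistent with using
α = 0.001 as the significance threshold. Per-permutation seeds are
derived from the root seed by counter (`SeedSequence([root, index])`), so
sweeps are pointwise reproducible and parallelizable. For modularity, Q
is Louvain-optimized with the same fixed restart count for observed and
mixed networks, with per-permutation child seeds.

Calibration: on pairs that are themselves exchangeable (generated by
edge-exchanging a common ancestor pair), the p-values are uniform — the
acceptance suite measures a Kolmogorov distance < 0.1 over 200 pairs at
n = 60, s = 0.2, 200 permutations, using global efficiency (the cheapest
metric; the exchange and thresholding path is identical for all three).

## Hub analysis

Degree correlation across sparsity is Pearson by default (a scatter of
two integer degree vectors with a linear fit; Spearman by flag), with NaN
returned for a constant degree vector. Degree-difference tables sort
descending with input-order tie-breaks; "bottom-5" means most negative,
not smallest magnitude. The envelope analysis sorts each permutation's
per-node degree-difference vector, producing per-rank min/max bands (plus
0.05/99.95 percentile bands, matching a two-sided 0.001 level);
exceedance is assessed per rank position, not per node identity, because
sorted curves are being compared.

## Synthetic data: what it emulates, what it does not

The generators produce: (a) modular weighted matrices — Gaussian weights
(SD σ) around μ_in within blocks and μ_out between, clipped at zero,
diagonal 1; (b) raw seed-count matrices — a base matrix with per-row
positive scale biases and optional non-negative noise; (c) subject
panels — Gaussian series with the planted matrix as population covariance
(repaired by clipping eigenvalues at 1e-10 if needed, logged) plus white
noise, random-walk motion traces (optionally one subject rescaled to a
3.5 mm peak to exercise the screen), and standardized random-walk WM/CSF
regressors; (d) volumes with constant-valued spheres painted in (later
sphere wins on overlap, logged).

Default study conditions mirror the reference analysis scale: 140 nodes
in four 35-node modules (μ_in = 0.6, μ_out = 0.2, σ = 0.1); panels of
240 frames at TR = 1.8 s; the "task" matrix derives from "rest" by adding
0.5 to a random 15% of between-module weights (long-range task coupling)
and 0.5 to every weight of one node (a planted task hub). Weight levels
were chosen so that within- and between-module weights are separated by
~4σ — structure dominates noise, as in group-level brain matrices — and
the boosted between-module edges compete with within-module edges at the
threshold, which is what makes the task graph more integrated and less
modular.

Not emulated: the meta-analytic sampling process itself (papers, foci,
smoothing kernels — only the resulting value maps), hemodynamics (no HRF;
series are white-in-time, so the 0.01–0.1 Hz filter removes power rather
than selecting a physiologically colored band), spatial preprocessing
(realignment, normalization), and spatial autocorrelation between ROIs.
Passing tests therefore show that the *pipeline* recovers planted
structure under realistic noise — not that real task and rest networks
differ; that conclusion depends on real data.

## Numerical conventions and degenerate inputs

Round-half-away-from-zero edge counts; lexicographic tie-breaks;
symmetry enforced at 1e-8 in the matrix container and repaired with a
warning at 1e-10 on file read; |r| clipped at 1 − 1e-7 before atanh;
constant time series and non-positive seed diagonals are errors naming
the ROI; empty and complete thresholded graphs are rejected; Q of an
empty graph is an error; a single-module partition has Q = 0 exactly.
One root seed drives everything; all child streams derive from it via
`SeedSequence` spawn keys, so results are independent of evaluation
order.

## Problem sizes in the shipped checks

The acceptance script runs the study at full node count (n = 140) with
200 permutations per test, 50 seeded replicate studies for power rates,
200×200 calibration pairs at n = 60, and a 21-subject panel (one planted
motion violator) at T = 240 — about one minute end to end on one CPU.
The routine test suite uses smaller replicate counts of the same checks.

## Known limitations

* Kendall matrices are computed pairwise via `scipy.stats.kendalltau`;
  at n = 140 and many subjects this is the slowest stage (O(n²·T log T)).
* Louvain is a greedy heuristic; restarts reduce but do not eliminate
  run-to-run partition variability across *different* seeds. Reported Q
  values are exact for the partition found.
* The G(n, m) reference does not preserve degree sequences; use the
  Maslov–Sneppen option when degree structure must be held fixed.
* The edge-exchange null conditions on the two observed edge sets; it
  tests network-identity exchangeability, not sampling variability of the
  underlying matrices.
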