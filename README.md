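# netshift

Compare the brain's **task coactivation network** with its **resting-state
network** over a shared set of regions of interest (ROIs), at matched
sparsity, with permutation-based inference.

The question behind the package: two brain regions that correlate strongly
at rest also tend to coactivate across task studies — yet the *global
configuration* of the two networks can still differ. Is the task network
more integrated (higher global efficiency), less clustered, less modular?
And do the hubs move? `netshift` implements the full analysis pipeline for
that comparison:

1. **Coactivation matrix** — per-seed meta-analytic coactivation values
   (one value map per seed ROI, extracted within 10 mm spheres, or a raw
   seed×target matrix) are row-normalized by each seed's self-coactivation,
   transformed by ln(1 + x), and symmetrized by averaging with the
   transpose. The diagonal of the result is ln 2 by construction, and the
   matrix is invariant to per-seed study-count biases.
2. **Resting-state matrix** — multi-subject ROI time series are screened
   for head motion (> 3 mm excluded), cleaned by OLS regression of 23
   nuisance regressors (6 motion parameters, their first-order derivatives,
   5 WM and 5 CSF eigenvectors, intercept), band-pass filtered to
   0.01–0.1 Hz, correlated with Kendall's tau-b, and averaged across
   subjects through Fisher's z.
3. **Matched-sparsity graph comparison** — both weighted matrices are
   binarized by keeping the top *m* = round(s·n(n−1)/2) weighted pairs at
   each sparsity s in 6–40% (1% steps), so the two binary graphs always
   have the same edge count. On these graphs the package computes, from
   scratch: global efficiency E = mean over ordered pairs of 1/d(i,j),
   mean clustering coefficient C̄ with C_i = 2t_i/(k_i(k_i−1)), and
   Newman's modularity Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j)
   optimized by the Louvain algorithm, plus G(n,m) and degree-preserving
   (Maslov–Sneppen) random references.
4. **Edge-exchange permutation null** — the edges private to each network
   are identified, a random half of each side is reassigned to the other
   network, and the metric difference is recomputed on the two mixed
   networks; repeating this (1000× by default) yields the null
   distribution for the observed task−rest difference (add-one, two-sided
   p-values; α = 0.001 by default).
5. **Hub-shift analysis** — degree correlations across sparsity, per-node
   degree-difference tables with top/bottom-5 hub lists (with MNI
   coordinates), and the sorted degree-difference curve against the
   min/max envelope of the permutation null.

Because the original inputs (an online meta-analysis database and a
public resting-state cohort) cannot ship with a package, `netshift`
includes a first-class synthetic-data module that generates all of them —
modular weighted matrices, biased seed×target count matrices, subject
time-series panels with motion traces and nuisance regressors, and
spherical-ROI value volumes — with planted structure that the pipeline
must recover.

## Worked example

```python
import netshift as ns

# planted study: rest = modular matrix (140 nodes, 4 modules);
# task = same + boosted between-module weights + a planted hub
task, rest, info = ns.make_task_rest_pair(seed=1)
print(f"weight correlation (9730 ROI pairs): r = {ns.weight_correlation(task, rest):.3f}")

res = ns.metric_difference_test(task, rest, s=0.20, metric="efficiency",
                                n_perm=200, seed=1)
print(f"global efficiency, task - rest at 20% sparsity: "
      f"{res.observed_diff:+.4f} (p = {res.p_value:.4f})")

res_q = ns.metric_difference_test(task, rest, s=0.20, metric="modularity",
                                  n_perm=200, seed=1, louvain_restarts=5)
print(f"modularity Q, task - rest at 20% sparsity:      "
      f"{res_q.observed_diff:+.4f} (p = {res_q.p_value:.4f})")

print(f"degree correlation at 20% sparsity: r = {ns.degree_correlation(task, rest, 0.20):.3f}")

table = ns.degree_difference_table(task, rest, 0.20)
top, _ = ns.top_bottom_k(table, k=5)
print(top[["label", "degree_a", "degree_b", "diff"]].to_string(index=False))
```

Output:

```
weight correlation (9730 ROI pairs): r = 0.709
global efficiency, task - rest at 20% sparsity: +0.1203 (p = 0.0050)
modularity Q, task - rest at 20% sparsity:      -0.4772 (p = 0.0050)
degree correlation at 20% sparsity: r = 0.212
  label  degree_a  degree_b  diff
m0_n000       120        30    90
m3_n111        36        25    11
m2_n073        31        23     8
m1_n045        34        27     7
m2_n092       38        31     7
```

Reading it: edge *weights* of the two networks agree closely (r = 0.71
over all 9730 pairs), yet at matched sparsity the task network is more
globally integrated (efficiency difference +0.12) and much less modular
(Q difference −0.48), both far outside the edge-exchange null (p equals
the minimum attainable at 200 permutations). Node *degrees* barely
correlate (r = 0.21) — the hubs are different — and the planted hub
`m0_n000` tops the degree-difference table with +90 more connections in
the task network.

## Command line

```sh
netshift simulate   --out sim --seed 1              # synthetic study inputs
netshift build-coact --raw sim/raw_counts.tsv --out coact.tsv
netshift build-rest  --panel sim/panel --out rest.tsv
netshift compare --a coact.tsv --b rest.tsv --sparsity 0.06:0.40:0.01 \
                 --n-perm 1000 --seed 1 --out results.tsv
netshift hubs    --a coact.tsv --b rest.tsv --sparsity 0.10,0.20,0.30 \
                 --n-perm 1000 --seed 1 --out hubs/
netshift run     --out run1 --seed 1                # everything end to end
```

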