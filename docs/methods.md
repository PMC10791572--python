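# Methods

This note documents the model, its parameters, the synthetic data used to
test it, and the design decisions taken where the procedure admitted more
than one reading. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Model overview and assumptions

`scqa` assumes that a cell type manifests in two complementary ways in a
genes × cells matrix:

1. **Qualitatively** — a block of genes is detected (non-zero) in the
   type's cells and largely absent elsewhere. Observed zeros inside the
   block are frequently dropouts, so binary mismatches where a gene is
   silent but the gene-cluster consensus is "on" are discounted by how dim
   the cluster is at that cell (the subsidiary vector
   `a_k = max(0.5 − mean member expression, 0)`, bounded in [0, 0.5]).
2. **Quantitatively** — genes of a block share an expression *trend*
   across cells up to monotone distortion ("quasi-trend-preserved" genes),
   captured by rank correlation and by value containment within per-cell
   quartile bounds of the cluster.

Both gene views are compressed into cells × landmarks matrices (binary Q1,
real-valued Q2). Cell clustering assumes that cells of one type form a
high-density region of the Q2 kNN graph and share a Q1 row; the method
does not require, and never estimates, a preset number of clusters.

No imputation is performed anywhere: dropouts are evidence, not missing
data. Cells are never filtered.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `filter_pct` (x) | 2.5 | drop genes detected in < x% or > (100−x)% of cells; bounds inclusive |
| `n_hvg` | 2000 | highly variable genes kept (all genes if fewer are available) |
| `rho` (ρ) | 0.7 | gene joins its best cluster only if similarity strictly exceeds ρ |
| `n_bins` (k) | 6 | expression bins; bin 1 is reserved for exact zeros |
| `alpha` (α) | 0.5 | convex weight between out-edge and in-edge evidence on the directed graph |
| `window_frac` | 0.05 | half-width of the pair-scoring window, as a fraction of the sorted gene list |
| `pair_keep_frac` | 1/1000 | fraction of all C(m,2) gene pairs kept as graph edges (floored; 1999 at m = 2000) |
| `quartile_pct` | 25 | order-statistic positions of the cluster bound vectors (quartiles) |
| `min_gene_cluster` | 3 | gene clusters below this size are discarded |
| `min_cell_cluster` | max(3, 0.01·n) | cell clusters below this size are dissolved before merging |
| `max_iter` | 50 | cap on propagation sweeps |
| k_out | 0.1·n (0.05·n for n ≥ 10⁴) | out-degree of the cell kNN graph, clamped to [1, n−1] |

All defaults are exposed through `ScqaParams` and the CLI.

## Design decisions

Where the procedure was genuinely open, the following choices were made
(each is a package decision, documented so it can be revisited):

- **HVG scheme.** Dispersion = variance/mean of raw values, z-scored
  within 20 equal-count bins of the log mean, ranked by z-score with ties
  broken by gene index. This is the standard binned mean–dispersion
  variant; any scheme that ranks variability relative to abundance would
  serve.
- **Scaling** is per-gene: `log1p` then division by the gene's maximum.
  Zeros stay exactly zero and every retained gene attains 1 somewhere.
  Per-gene (rather than global) scaling makes per-cell averages of member
  genes — the landmark templates — comparable across genes.
- **Template re-binarization.** After a gene joins a qualitative cluster
  the member-mean template is fractional; the equality test of the
  three-case similarity uses its binarization at 0.5 (≥ 0.5 → 1), keeping
  the three cases well defined.
- **Subsidiary vectors use scaled expression values** of the members (not
  binary values), so "dimness" is measured on the [0, 1] expression scale.
- **Singleton growth.** A gene that fails the ρ threshold opens a new
  cluster that *can* attract later genes in the same sweep; pruning
  happens after the sweep. An optional `rho_schedule` re-sweeps the freed
  genes at lower thresholds (off by default; one sweep at ρ = 0.7).
- **Spearman on binned rows.** LC₂ scores gene pairs on the discretized
  matrix (average ranks for ties); a constant row correlates 0.
- **Containment bounds are inclusive**, and the per-group pair budget has
  a floor of one pair. The quartile order statistics use 1-based indices
  `max(1, ⌊q·|C|⌋)` and `min(|C|, ⌈(1−q)·|C|⌉)`; note the member **mean**
  can exceed the upper order statistic on skewed data (e.g. members
  0,0,0,1 at a cell), so `lower ≤ template ≤ upper` is *not* an invariant
  and is not asserted — only `lower ≤ upper` is.
- **Density** uses out-neighbors only: they form the constructed kNN set,
  so every node averages over exactly k_out edges.
- **Zero-denominator convention.** Any term of the two-hop similarity (or
  of the node-to-unlabeled similarity) whose neighbor intersection is
  empty contributes 0 — "no paths, no evidence" — rather than NaN.
- **Seed candidates** qualify at density ≥ β (boundary inclusive), and the
  mutual-neighbor merge is applied transitively (connected components of
  the mutual graph over candidates).
- **Convergence loop.** Propagation sweeps repeat until a full sweep makes
  no assignment, both after seeding and again after pruning/merging.
  Expansion then labels every remaining node in one pass. Re-running
  propagation afterwards is a no-op (the unlabeled set is empty), so the
  labeling is final. A reassignment-style refinement over already-labeled
  nodes was tried and rejected: on data where within-type similarities are
  nearly equal it moves nodes on ~10⁻³ weight differences and destabilizes
  correct clusters.
- **Expansion reference level.** The "average number of neighbors within
  the cluster" A(C_j) is computed over the *still-unlabeled* nodes:
  `A(C_j) = mean_i |ON_i ∩ C_j|` for unassigned i. A node therefore joins
  the cluster where it is better connected than the typical unassigned
  cell, and isolates itself only when below average everywhere. The
  members'-internal-degree reading (`Σ_{r∈C} |ON_r ∩ C| / |C|`) was
  implemented first and is degenerate: for a coherent cluster it
  approaches k_out, which no outside node can reach while coverage is
  partial, stranding large fractions of cells as singletons. Candidate
  clusters and reference levels are a snapshot taken at entry, so clusters
  founded during expansion never compete for subsequent nodes (otherwise
  a fresh cluster with A = 0 absorbs everything after it).
- **Ablation plumbing.** `lc1_only` builds the graph and weights from Q1;
  `lc2_only` seeds from Q2 binarized at 0.5 (the same threshold as the
  qualitative templates) and propagates on Q2.
- **Pearson of a constant row** is defined as 0 against everything.
- **Bin edges.** Discretization backs off bin boundaries by 10⁻⁹ so that
  values sitting on an edge up to float round-off (e.g. 0.8·5 =
  4.000…0004) fall in the closed upper end of the lower bin.
- **Ties everywhere** break by ascending index (genes, cells, cluster
  labels); sorts are stable. The pipeline contains no randomness, so two
  runs on the same input produce byte-identical outputs.
- **ARI degenerate case**: when max-index equals expected index (both
  partitions trivial), ARI is 1 if the partitions are pair-identical and
  0 otherwise. Entropies use natural logs; the NMI ratio is base-free.

## Synthetic data

The generator (`scqa.synthetic`) emulates the features the pipeline
actually keys on, at CI scale (defaults: 5 types × 100 cells, 550 genes,
< 1 s end to end):

- per-type **marker blocks** (30 genes/type): lognormal(1.0, 0.5)
  positives in the type's cells, zero elsewhere except a 1% leak;
- **housekeeping genes** (100): lognormal(3.0, 0.3) levels, positive in
  every cell. Being highly expressed they suffer negligible dropout and
  are detected in ≈ all cells — which is exactly why the (100−x)% ubiquity
  filter removes them, as it does in real data;
- **noise genes** (300): detection probability U(0.4, 0.7), low lognormal
  positives — a stand-in for the non-marker tail of an HVG panel. The
  tail is deliberately sized so the working panel (~550 genes) gives the
  one-thousandth pair-retention rule a workable edge budget; at ~250
  genes the budget (≈ 27 edges per gene group) cannot seed a cluster for
  every planted type, a small-scale artifact rather than a property of
  the method's intended ~2000-gene regime;
- **per-cell library size**: a lognormal(0, 0.3) factor multiplying every
  gene of a cell. Without it all cells of a type are exchangeable draws,
  within-type similarities are equal up to noise, and the propagation
  rule "join if S(node, cluster) strictly beats S(node, unlabeled)"
  degenerates into a coin flip;
- **mean-dependent dropout**: each entry of gene g is zeroed with
  probability `shape · σ(−(log1p(μ_g) − log1p(m₀))/s)` where μ_g is the
  gene's mean over expressing cells, m₀ = 2.0, s = 0.3, shape = 0.4 —
  markers lose ~10–20% of their within-type entries, dim noise genes
  more, housekeeping essentially none. `dropout_shape = 0` disables
  excess zeros.

A separate helper builds **quasi-trend blocks**: genes that follow one
base profile up to a gene-specific power transform (exponent U(0.5, 2.0))
and small noise applied only where the base is positive, preserving the
zero pattern and approximate rank order.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, UMI-depth/count discreteness, trajectories, or correlated non-marker
structure. Passing tests on these fixtures therefore demonstrates that the
implementation realizes the method's mechanics and recovers planted
structure in its intended regime — not that the method succeeds on any
particular real dataset.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on hand-built matrices (≤ 30 × 25) and on the
default 550 × 500 simulation. Oracle-equivalence checks use random
digraphs of ≤ 20 nodes (exhaustive path enumeration) and partitions of
≤ 200 items (quadratic pair loop). The acceptance script uses the
2000-gene binary matrix for the edge-retention constant, five simulations
of 500 cells for recovery/ablation/determinism, and a 240-gene × 240-cell
quasi-trend fixture for landmark coherence; the whole script completes in
seconds.

## Known limitations

- The two-hop similarity is O(k_out²) per node-cluster evaluation and the
  weight matrix is dense (n × n); the implementation is comfortable to a
  few thousand cells but has not been engineered for the ≥ 10⁵-cell
  regime.
- With ~70–80% zeros, the zero-zero agreement term of both gene
  similarities sits near ρ = 0.7; very sparse panels (marker detection
  ≪ 20% of cells) can merge unrelated sparse genes into low-information
  landmarks. The gene filter mitigates this but cannot eliminate it.
- Landmarks fragment along dropout sub-structure (typically ~2 landmarks
  per planted type rather than 1); downstream cell clustering is robust
  to this, but landmark counts should not be read as type counts.
- `lc2_only` seeding binarizes Q2 at 0.5; for data whose landmark
  consensus hovers near 0.5 the resulting cell groups are unstable.
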