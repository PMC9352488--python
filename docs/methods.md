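# Methods

This note documents the statistical procedures, the synthetic-data model
the tests rely on, the numerical conventions, and the design choices made
where more than one reasonable reading existed. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## 1. Cluster differential abundance

Input is a per-cell table with a cluster label and a two-level condition
(`T2DM` / `normal`). For cluster c with n_cT disease cells of N_T total and
n_cN control cells of N_N total:

- effect size: FC = (n_cT/N_T)/(n_cN/N_N), the ratio of
  condition-normalized proportions. No pseudocount is added; an empty
  control cluster gives FC = ∞ (logged) and the cluster is selected on its
  p-value alone.
- significance: two-sided Fisher exact test on
  [[n_cT, N_T−n_cT], [n_cN, N_N−n_cN]] (scipy), validated against a
  hypergeometric enumeration oracle.
- selection: (FC > 4 or FC < 0.25) and raw p < 0.05. Raw p is used for
  selection because that is how the thresholds are conventionally quoted;
  a Benjamini–Hochberg column is reported alongside for transparency.
- swapping condition labels maps FC → 1/FC and leaves p unchanged (tested).

QC bounds are inclusive for the gene-count window (100 ≤ genes ≤ 7500) and
strict for mitochondrial content (< 35%) and UMI count (> 1000); all four
are configurable. Log-normalization is v → ln(1 + v·s/C) with scale factor
s = 10 000 and column total C.

Marker detection compares each cluster against all other cells with a
two-sided rank-sum test on normalized values; log2FC uses a pseudocount of
1e−9, and the reporting thresholds are log2FC ≥ 0.5,
max(pct_in, pct_out) ≥ 0.35, p < 0.05. The test is a plain normal-
approximation rank-sum on the normalized matrix — it emulates the standard
thresholds without reproducing any particular toolkit's internals.
Clusters with fewer than two cells on either side are skipped with a
warning.

## 2. Dense-module detection (MCODE)

The three stages follow the original algorithm description:

1. **Vertex weighting.** For node v, take the subgraph induced by v and its
   neighbors, find its highest k-core by core numbers (equivalently,
   minimum-degree peeling — the test oracle peels independently), and set
   weight(v) = k × density(core), density = 2E/(n(n−1)).
2. **Expansion.** Seeds in descending weight (ties broken
   lexicographically by node id, so runs are deterministic); breadth-first
   admission of neighbors with weight ≥ seed·(1 − VWP), VWP = 0.2 by
   default. A vertex assigned to a complex is never re-seeded nor assigned
   again.
3. **Post-processing.** Haircut (default on) takes the 2-core of the
   complex — iterated removal of singly connected members; if that
   disconnects the complex, the component containing the seed is kept so
   complexes always induce connected subgraphs. Fluff (default off) adds
   boundary neighbors with closed-neighborhood density above 0.5; fluffed
   members may overlap complexes. Complexes with fewer than two members are
   dropped.

Scores are density × size; output is sorted by descending score. The
parameter values (VWP 0.2, haircut on, fluff off) are the common tool
defaults and are exposed as arguments.

`prune_low_degree` is single-pass by default — it removes nodes below the
degree threshold from the induced subgraph exactly once, reflecting a
one-shot "remove weakly connected genes" cleanup; an `iterate` flag peels
to a fixed point instead.

Edge-confidence filtering keeps edges with score strictly above the
threshold; scores on a 0–1000 scale are auto-detected (any score > 1) and a
unit-scale threshold is rescaled, so 0.4 means 400 in that dialect.

## 3. Diagnostics and correlation expansion

- AUC via the rank-sum identity with midranks for ties, checked against a
  brute-force concordant-pair oracle. Reported AUC is max(a, 1−a) with the
  direction recorded, matching the convention of reporting AUC ≥ 0.5; note
  this inflates the *null* mean AUC above 0.5, which the tests account for
  by comparing against the oracle's oriented expectation.
- Wilcoxon rank-sum: exact enumeration when combined n ≤ 12 and no ties,
  else normal approximation with tie and continuity corrections. The
  switch point is configurable.
- Hub selection: differential significance (p < 0.05) is required first,
  AUC ranks second, ties break on gene id. "No differential candidate" is
  a legitimate no-hub outcome, distinct from an error.
- Expansion: Pearson r with the t-distribution p-value (n−2 df). The
  selection threshold is **signed** (r > 0.95, p < 0.001) by default, since
  a co-expression module recruited around an up-regulated hub is positively
  correlated; an `absolute` flag selects on |r| instead. Zero-variance
  genes yield NaN and are never selected.
- Cell-type fraction correlation takes a deconvolution matrix as input
  (cell types × samples) and reports r, p and a significance tier
  (p < 0.05/0.01/0.001) per (gene, cell type).
- Benjamini–Hochberg is the standard step-up with monotonicity enforcement
  (statsmodels), validated against a textbook reimplementation.

## 4. Network proximity

Distances are unweighted hop counts from multi-source BFS (validated
against Floyd–Warshall). The closest distance is averaged over targets;
the weight ω_t = −ln(D_t + 1) applies iff target t is in the disease set.
**D is read as the degree of the target in the interaction network** — the
natural reading in the network-medicine literature, and the one that makes
ω a fixed per-node quantity; an `omega_zero` mode disables weighting for
sensitivity analysis.

Null model: reference sets R of size |T ∩ network| drawn uniformly without
replacement (1000 draws by default), each scored with the *same* weighted
distance — ω enters the null exactly as it enters the observed value, so
numerator and denominator of the z-score are on the same scale. The sample
sd uses the n−1 denominator; a degenerate null (σ = 0) is flagged, with
z = 0 when d = μ and ±∞ otherwise. A degree-binned matched null is
available behind a flag but off by default, because the procedure is
defined by size matching alone.

Computation runs on the largest connected component by default
(configurable), avoiding infinite-distance artifacts; targets unreachable
from S are excluded from the average with their count logged, and a drug
with no reachable target is reported but excluded from ranking.

Significance is the one-sided lower-tail normal probability of z (being
*closer* than random is the signal); "global FDR" is Benjamini–Hochberg
across all screened drugs, with candidates at FDR < 0.001. Ranking is by
ascending z, then ascending d, then drug id — z is preferred as the
primary key because it is the normalized proximity the screen is built
around, while raw d is incomparable across drugs with different target
counts.

Per-drug null draws derive from independent child streams of the single
configured seed (spawned in sorted drug order), so screens are reproducible
and independent of dictionary ordering.

## 5. Synthetic-data model

The generator is a pure function of (config, seed); every stream is an
independent child of the seed, and identical configs give byte-identical
outputs (tested, including a full pipeline rerun).

- **Network:** preferential-attachment (Barabási–Albert) background with
  n = 500 nodes and m = 2 edges per new node — heavy-tailed degrees like a
  real interactome — plus planted cliques (sizes 8 and 6 by default) on
  disjoint random node sets; edge confidences are uniform on (0, 1].
- **Bulk expression:** standard-normal noise, 9 samples per group (a
  two-group design of 18 samples, the scale of a small patient cohort).
  Group-discriminative genes get +3 SD in the disease group. The
  co-expression module follows x = λf + √(1−λ²)ε with a per-sample factor
  f and λ = 0.99, so the expected pairwise module correlation is
  λ² = 0.98 — above the 0.95 selection threshold with analytic margin. In
  the wired-together dataset (`generate_all`) the discriminative plant
  covers the whole module: hub and module share both the group shift and
  the factor. A shift planted on the hub alone would add variance
  uncorrelated with the factor and attenuate the hub–module correlation to
  roughly λ²/√(1 + e²/4) ≈ 0.54 at e = 3, below any usable threshold — the
  co-expressed disease module *is* the differential signal, as in real
  disease modules.
- **Cells:** 2000 cells per condition across 11 clusters with a heavy-head
  composition; the enriched cluster's probability is multiplied by 20 in
  the disease condition and renormalized (observed proportion-ratio FC ≈ 6
  for the default composition). QC metrics are drawn inside the passing
  ranges, with a 10% fraction of cells given exactly one out-of-range
  metric.
- **Cell-level expression:** Poisson(0.3) background over 60 genes with
  three planted markers per cluster (rate +3 inside the cluster). This
  matrix exists so the marker stage and the end-to-end pipeline have
  cell-resolution input; it makes no attempt at realistic count
  distributions.
- **Drugs:** 50 background drugs with 5 targets drawn uniformly from the
  network, plus one planted drug whose targets sit inside the disease
  module (all 5 by default; partial overlap places the remainder on
  adjacent nodes).

What passing tests do **not** show about real data: the generator has no
dropout or library-size structure in the single-cell matrix, no
batch/covariate effects in bulk expression, no correlated edge noise or
literature bias in the network, and drug target sets are size-homogeneous.
Plant-recovery rates quoted by the tests are properties of these idealized
conditions.

## 6. Numerical conventions and problem sizes

- Fisher exact p compared to enumeration at relative tolerance 1e−6;
  enumeration includes tables with probability ≤ observed × (1 + 1e−7).
- Exact/approximate rank-sum switch at combined n = 12.
- Pipeline outputs are plain TSV; the manifest records version, config
  hash, seed, and per-stage row counts and timings (timings are the one
  run-to-run difference; determinism is asserted over the result tables).
- Test problem sizes: oracle suites run 200–1000 random instances on
  graphs/samples of ≤ 8–10 elements; null calibration uses 1000
  pseudo-drugs × 1000 null draws on the default 500-node network; plant
  recovery uses 100 seeds per stage. These sizes give the stated
  calibration bands comfortable margins while keeping a full run around a
  minute on one core.

## 7. Known limitations

- The marker test reuses the asymptotic rank-sum path even for tiny
  clusters (the dedicated exact branch is available via
  `wilcoxon_rank_sum` but not vectorized across genes).
- MCODE's fluff stage admits overlap but no scoring adjustment; complexes
  are not re-scored after fluffing beyond the density × size convention.
- The proximity null treats the target-set size as the only matched
  property by default; strongly hub-biased target sets will look proximal
  to everything — use the degree-matched flag to probe that.
- Selection rules are threshold-based to mirror the conventions they come
  from; none of the thresholds is adaptive.
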