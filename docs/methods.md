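# Methods

## Model

Functional inference from amplicon data is treated as a linear map. A
pre-built genome content network supplies matrix **A** (functions ×
microbes): `A[i][k]` is the copy number of gene family *i* in the genome
associated with reference microbe *k*. A taxonomic profiler supplies matrix
**B** (microbes × samples): `B[k][j]` is the count (or relative abundance)
of microbe *k* in sample *j*. The prediction is the plain product
`C = A · B`, i.e. every read assigned to a microbe contributes that
microbe's full gene repertoire to its sample. Assumptions inherited from
this formulation: gene content of a taxon is fixed across samples (no
strain-level variation), unmapped taxa contribute nothing, and abundances
combine additively.

`C` is exact linear algebra, not an estimate — all approximation lives in
**A** (how well reference genomes represent the observed taxa, summarized
by NSTI below) and in **B** (read mapping, done upstream of this package).

## Out-of-core execution

The streamed path computes the identical product under two byte budgets:

* **System RAM → iterations.** Samples are processed in chunks of at most
  `iteration_size`; an anchor table maps RAM to a recommended size
  (16 GiB → 10,000; then linear at 1,562.5 samples/GiB: 32 → 50,000 …
  640 → 1,000,000), clamped below the smallest anchor, extrapolated at the
  same slope above the largest, rounded down to a multiple of 1,000. The
  16 GiB anchor deliberately sits below the linear rule (loading overheads
  dominate on small machines) and is kept as a printed special case.
* **Device budget → partitions and batches.** A `reserve_fraction`
  (default 0.05) is held back for intermediates. Of the remainder, at most
  `a_fraction` (default 0.70) may hold **A**; if **A**'s dense
  single-precision footprint exceeds that, the microbe axis is split into
  the smallest number of near-equal contiguous partitions whose largest
  member fits. The partition count is computed as
  `ceil(n_microbes / floor(a_budget / column_bytes))` rather than
  `ceil(bytes(A) / a_budget)`: the two agree except when the budget is not
  an integer multiple of one microbe-column's bytes, where only the former
  guarantees every partition actually fits. The leftover budget sets the
  sample batch size with a per-sample cost of `4·(partition_microbes +
  n_functions)` bytes — the **B** row-slice plus the resident **C**
  accumulator column — so batches provably fit.

The footprint model is `rows × cols × 4` bytes (single precision), with
GiB = 2³⁰; this uniquely reproduces the published sizes of the five standard
full-length 16S reference GCNs (5.12, 17.08, 7.85, 5.22, 1.27 GiB at 13,839
functions), which is why 4 B/element and the binary GiB are the defaults.

### Determinism

Work units are (partition, sample-batch) pairs, assigned round-robin to
workers within a partition stage (remainders to lower worker ids); a barrier
separates stages. Each batch's output columns are owned by exactly one unit
per stage, and partition partial products accumulate in ascending partition
index into a float64 block. The floating-point accumulation order is
therefore fixed by the plan alone: one worker and W workers give
bit-identical results, and the degenerate 1-partition/1-batch plan is
bit-identical to the dense product. The multiply primitive is pluggable
(`engine.BACKENDS`); the dense NumPy path is the reference, and any
accelerated backend must pass the same oracle suite. Worker parallelism uses
threads (NumPy's matmul releases the GIL).

Interrupted streamed runs log a resume cursor at each iteration boundary.
For column-chunked TSV input the cursor is the sample offset (chunks are
re-read with column selection), not a byte offset.

## GCN construction

Given a phylogeny with branch lengths, known trait vectors (gene copy
numbers) on reference tips, and a set of query tips:

* **Collapsing.** Genomes with byte-identical 16S sequences form one
  cluster represented by the lexicographically smallest member id; the
  representative trait vector is the members' arithmetic mean, so cluster
  size × representative preserves totals exactly.
* **Hidden-state prediction.** A query's traits are a weighted average of
  reference traits, weights `w_r = 1/(d_r + 1e-9)` (inverse-distance,
  default) or `w_r = exp(-d_r)` (exponential-decay), with `d_r` the
  patristic distance. If any reference sits at distance 0, the prediction is
  the plain mean over the zero-distance references. Predictions are convex
  combinations of reference rows, hence bounded by reference minima/maxima
  elementwise — a deliberate bias-for-stability trade-off. This is *not* a
  continuous-time Markov ancestral reconstruction: it cannot extrapolate
  beyond observed trait ranges and ignores the tree topology between
  references, but it is fast, parameter-free and monotone in distance. The
  1e-9 regularizer only matters within floating-point noise of an exact tip
  match, which the zero-distance rule already handles.
* **NSTI.** Each query records its minimum patristic distance to any
  reference (ties to the smallest reference id); references record 0. The
  per-sample *weighted NSTI* is the abundance-weighted mean
  `Σ b_k d_k / Σ b_k` — scale-invariant in the abundances and bounded by the
  min/max distance among microbes present, so it reads directly as "average
  evolutionary distance to the nearest sequenced genome, weighted by who is
  actually in the sample". Taxa dropped at alignment are excluded from both
  numerator and denominator; their abundance fraction is logged.

Weighted NSTI is computed on the abundances as given (raw or relative —
equivalent by scale invariance), before any optional 16S copy-number
normalization. Copy-number normalization of **B** (`B'[k][j] =
B[k][j]/copies_k`) is exposed as an explicit optional step, off by default,
because it commutes with inference only as a column-wise rescaling of **A**
and different upstream profilers disagree on whether it has been applied.

## Pathway aggregation

KO-level rows roll up to pathway-level categories by summation; a KO in
several pathways contributes fully to each (the KEGG BRITE convention), so
the pathway matrix over-counts relative to the KO matrix. The identity that
does hold, and is tested: pathway total + unmapped bucket =
multiplicity-weighted KO total. Unmapped KOs are reported separately and
excluded from pathway rows. Relative-abundance normalization leaves all-zero
sample columns at zero with a warning.

## Synthetic data

The generators exist to exercise numerics and contracts offline, all pure
functions of (parameters, seed) with fixed per-generator seed offsets:

* `make_gcn`: iid Bernoulli(density) mask × uniform integer copy numbers in
  [1, copy_max]. Defaults (200 × 500, density 0.3, copy_max 30) are a
  desk-scale stand-in for real GCNs (~10⁴ × 10⁵).
* `make_abundance_table`: per-entry dropout at rate `sparsity` (default
  0.5) over rounded log-normal counts (σ = 1), scaled so the expected
  per-sample total is `mean_depth` (default 10,000 — a typical 16S library
  size); all-zero samples are redrawn.
* `make_tree_with_traits`: random sequential-join bifurcating topology,
  exponential branch lengths (mean 0.1 substitutions/site, the order of
  within-family 16S divergence), traits evolving from a Uniform(2, 8) root
  vector by Gaussian steps with sd = branch length × smoothness (default
  3.0), clipped at 0. Smoothness 3.0 puts per-edge trait drift at roughly
  10% of the root scale, giving a strong but not degenerate phylogenetic
  signal.
* `make_nsti_distances`: a fraction of taxa at distance 0 (sequenced
  references), the rest exponential with mean 0.05 — matching the
  right-skew of real NSTI distributions.

What these fixtures do *not* emulate: compositional correlation structure,
taxon co-occurrence, realistic rank-abundance curves, strain heterogeneity,
or any ecology. Passing tests therefore demonstrate numerical and
contractual correctness of the pipeline, not predictive accuracy on real
communities — the latter depends on reference-database coverage, which NSTI
only flags.

## Problem sizes and numerical tolerances

The oracle suite compares streamed against dense inference on 108 random
fixtures (up to 500 functions × 1,000 microbes × 200 samples) across every
combination of partitions {1,2,5} × batch sizes {1,7,all} × workers {1,2,4}
× iteration sizes {1,13,all}, at an elementwise relative tolerance of 1e-5
(generous: with float64 accumulation the observed discrepancy is 0 except
for ordering effects at extreme partition counts). A larger self-consistency
run uses 200 × 500 × 10,000 samples with forced partitioning, batching and
multiple iterations — the package's own desk-scale proxy for at-scale
behaviour. Trait-recovery checks use 40 references / 10 held-out queries /
20 traits and require Spearman ρ ≥ 0.8 between predicted and true query
traits (typical values ≈ 0.9 across seeds).

## Degenerate inputs and tie-breaks

Zero-sample tables produce empty (functions × 0) profiles without error;
all-zero sample columns propagate to zero output columns (and NaN weighted
NSTI, with a warning). Zero-length branches are allowed (negative ones are
rejected at parse time); exact distance ties break lexicographically; rank
ties in `top_n_features` break toward the smaller id. Table text output uses
shortest round-trip decimals, so write→read is bit-stable.

## Known limitations

* No GPU kernels are shipped; the backend registry is the seam where an
  accelerated implementation would plug in, and wall-clock throughput at
  10⁵–10⁶ samples is out of scope for the reference backend.
* The HSP is a distance-weighted average, not a phylogenetic model;
  agreement with model-based reconstructions is neither claimed nor tested.
* The streamed TSV reader re-scans the file per iteration (column
  selection); a column-chunked binary layout would be needed for truly
  I/O-bound workloads.
* ASV denoising and sequence-to-reference mapping happen upstream; the
  package consumes already-mapped tables and only offers exact-id alignment
  with a dropped-abundance report.
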