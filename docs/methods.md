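# Methods

## Ontology handling

The GO graph is restricted to `is_a` edges; `part_of` and other relationship
types are ignored, obsolete terms are dropped, and `alt_id` aliases are
mapped to canonical ids during annotation lookup (mapped counts are logged,
since curated datasets may or may not contain them). Each namespace (MFO,
CCO, BPO) must have exactly one parent-less root. Annotation records are
kept only when supported by an experimental/curated evidence code
(EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP by default);
proteins with no surviving record are dropped.

True-path propagation replaces every protein's term set by its ancestor
closure up to and including the namespace root; the operation is idempotent
and its output is a consistent sub-graph of the DAG. Label spaces keep the
terms of one namespace annotated in at least `min_count` proteins
(30 for MFO and CCO, 60 for BPO by convention in the intended full-scale
workflow; small fixtures use smaller thresholds), always excluding the
namespace root. Term order is topological with a lexicographic tie-break so
label matrices are identical across runs.

**Information content.** `I(v) = −log₂ n(v)/n(Pa(v))`, where `n(v)` counts
proteins annotated with `v` and `n(Pa(v))` counts proteins annotated with
*all* parents of `v`. The joint-parent denominator is the natural reading
for propagated sets, where `v` implies every parent; a term co-extensive
with its parents gets exactly 0 bits. No smoothing is applied — the label
threshold guarantees positive counts, and a zero denominator raises rather
than silently clamping.

**Score propagation.** Predicted scores are made hierarchically consistent
by assigning every term the maximum over itself and all of its in-space
descendants. Because the stored ancestor sets are transitively closed, one
pass is exact; the operation is idempotent and never decreases a score.
Propagation stops at the label-space frontier (roots are outside every
space and receive no score).

## The latent tensor reconstruction model

Shapes and constraints: per view `d`, `U⁽ᵈ⁾ ∈ R^{n_x_d × k_d}` with
unit-norm rows, per-feature scales `scale⁽ᵈ⁾` (the diagonal of `D⁽ᵈ⁾`),
`V⁽ᵈ⁾ ∈ R^{n_t × k_d}` with unit-norm rows; core weights `λ ∈ R^{n_t}`
(unconstrained in sign); output projection `Q ∈ R^{n_y × n_t}` with
unit-norm columns. The output is computed as `π(x) = Q s` with
`s = λ ⊙ Π_d h⁽ᵈ⁾` — the only shape-consistent arrangement of the
projection given the column-norm constraint.

- **Inner dimension `k_d`** defaults to `min(n_t, n_x_d)`; it is a free
  hyperparameter of the second-level factorization.
- **Constraint handling** is projected gradient: after each epoch the rows
  of `U⁽ᵈ⁾`/`V⁽ᵈ⁾` and columns of `Q` are renormalised; zero rows are
  replaced by seeded random unit vectors (logged). Residuals after every
  epoch are recorded in the training report and stay at machine precision.
- **Gradients** are derived analytically (plain numpy); the optimiser is
  Adam by default (step 1e-3 in the estimator; verification experiments use
  1e-2, chosen once for the small dense problems they run), batch 128.
  Mini-batch order is reshuffled per epoch from the run seed, so training
  is bit-reproducible.
- **Activations** `A` (inside `U⁽ᵈ⁾ᵀ`) and `B` (outside `V⁽ᵈ⁾`) are
  identity or ReLU. With identity activations the model is exactly a CP
  tensor contraction and is verified against an explicit dense tensor; with
  ReLU it is positively homogeneous per view.
- **Score post-processing**: outputs are clipped to [0, 1] before
  thresholding (targets are binary under squared error); a flag disables
  the clip.
- **Regularisation**: only `λ` is penalised, with weight `C_λ/(2 n_t)`;
  the per-batch regulariser gradient is scaled by the number of batches so
  one epoch applies the full-objective gradient once.
- **Validation selection**: when validation ids are given, the model with
  the lowest validation objective across epochs is returned; the pipeline
  then refits on train+validation before scoring the test fold (a flag
  disables the refit for smoke runs).

Non-convexity: the CP objective has local optima. The planted-recovery
verification uses the standard multi-start protocol — three seeded
initialisations, keeping the run with the lowest final training objective —
applied unconditionally at every seed.

## Autoencoder view reduction

Sparse high-dimensional views (binary domain fingerprints, PPI adjacency
rows) are compressed by a symmetric autoencoder: four encoder layers
(`[n_x, 4096, 2048, target]` by default, scaled down automatically for
small inputs; the published description fixes only the depth and ReLU) and
a mirrored decoder, ReLU between layers, linear bottleneck and output, mean
squared reconstruction loss (binary cross-entropy optional for 0/1 data),
Adam with seeded shuffling. The intended full-scale target dimension is
1000; tests use single-digit bottlenecks. Fingerprint vocabularies are
fixed from the training split only; unseen test features are dropped.

## Cross-validation

Splits are grouped by sequence cluster (as produced by clustering at 30%
identity in the full-scale workflow), never by protein: clusters are
shuffled with the split seed and dealt round-robin into `n_folds` test
groups, and the validation carve-out (~10% of training clusters) is also
cluster-wise, preserving homology separation on both boundaries. A cluster
is never split across train+validation and test.

## Metrics

Thresholds run over the CAFA grid 0.01…1.00 (step 0.01). Precision at τ
averages over the `m(τ)` proteins with at least one call; recall averages
over **all** test proteins; thresholds with no called protein are skipped
for precision-based metrics but still participate in `S_min` (no calls
means `mi = 0`, `ru` = average total true IC). Proteins with empty true
sets contribute recall 1 and are excluded from `ru` (their count is
logged). `ru`/`mi` follow the prose semantics — `ru` is the IC of false
negatives, `mi` the IC of false positives. AUPRC is the step sum walked
from the highest threshold down with recall anchored at 0, so a perfect
predictor scores 1 exactly. AUROC is micro-averaged over all protein-term
pairs and computed as the exact mid-rank statistic (ties count one half),
the limit of the threshold step sum. All metrics are invariant to protein
and term order.

## Baselines

- **Naive**: every test protein receives each term's training-set relative
  frequency.
- **BLAST-full**: copies the entire label row of the best-scoring training
  hit (max bit-score; ties broken by min e-value, then lexicographic
  subject id — the tie order is this package's choice); queries without
  hits get zero rows, which lowers coverage.
- **BLAST-partial**: `score(i, j)` is the maximum percent identity (divided
  by 100 to share the [0,1] threshold grid) over hits from query `i` to
  training proteins annotated with term `j`.

Hit tables are consumed as standard 12-column tabular alignment text,
filtered at e-value ≤ 0.001. Alignment computation itself is external;
tests and experiments use synthetic hit tables.

## Synthetic data generator

The generator emulates the full input surface at desk scale: a single-root
layered is-a DAG (default depth 3, branching 4, 20% multi-parent nodes)
written as OBO 1.2 text; a planted CP model with `|λ_t| ≥ 0.1` so the
signal is identifiable; i.i.d. standard-normal views (Bernoulli(0.1)
optional for binary views); and labels derived from the planted model's
scores — min-max scaled per term, max-propagated up the DAG, thresholded at
a per-term quantile (default 0.8, i.e. ~20% positives per term), then
re-closed upward because per-term thresholds alone can break closure.
Optional label noise flips entries and re-closes (additions pull in
ancestors, removals drop in-space descendants), so generated label matrices
are ancestor-closed under all settings. Clusters are seeded random
assignments with every cluster non-empty (default 37 clusters, mirroring
the audit size used in verification).

What the generator does **not** emulate: real embedding geometry, sequence
composition, the long-tailed term-frequency distributions of curated
corpora, or correlated noise between views. Passing tests on synthetic
bundles therefore demonstrates correctness of the machinery and the
qualitative model-versus-baseline ordering, not the headline accuracy
attainable on curated full-scale datasets with pretrained embeddings.

## Verification experiment sizes

Chosen once as the package's study conditions: tensor-oracle agreement on
100 random models (≤3 views, dims ≤5, rank ≤4); planted recovery with 2
views of 20 features, rank 3, 2000 training / 500 held-out samples, 500
epochs; metric oracles on 50 random fixtures (≤10 proteins × ≤8 terms);
consistency audits on 100 random DAGs; the benchmark bundle with 30
non-root terms, 1000 proteins, 2 views, a rank-3 plant fit at rank 8 for
100 epochs; split audits with 200 proteins in 37 clusters over 10 folds.

## Known limitations

- The trainer is dense-numpy; very wide views should be reduced first.
- `explicit_weight_tensor` is guarded at 10⁶ entries and exists for
  verification, not production inference.
- Per-term min-max scaling of planted scores makes synthetic label
  prevalence roughly uniform across terms, unlike real GO corpora.
- AUROC is micro-averaged only; term-centric evaluation modes are out of
  scope.
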