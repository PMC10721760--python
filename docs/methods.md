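# Methods

## The profile model

A phylogenetic profile treats each reference gene as a vector of best-hit
bit-scores across a panel of proteomes. Bit-scores scale with alignment
length, so each row is normalized by the gene's self-alignment score
(LPP = BS / BS_self ∈ (0, 1]); panel species differ systematically in
divergence from the reference, so each species column is then Z-scored
(NPP). After both normalizations, a positive NPP entry means "this gene
is better conserved in this species than the average reference gene",
which is the unit of co-evolution the downstream clustering compares.

Filters (constants of the analysis, all configurable in
`PipelineConfig`):

| constant | default | rationale |
|---|---|---|
| min protein length | 40 aa | sub-40-aa entries are mostly annotation noise |
| min self-score | > 80 bits | weak self-alignments make LPP unstable |
| score floor | 24.6 bits | bit-score of E = 0.05; below it a hit is indistinguishable from chance, and absent hits are coded as the floor |
| min other-proteome support | 5 | a gene above the floor in < 5 species has no profile to correlate |

Z-scoring uses the sample standard deviation (ddof = 1). Columns with
zero spread are set to all-zeros and flagged, not dropped, so species
indices stay aligned with the clade map. Filter order is length →
self-score → floor → support; membership of the retained set does not
depend on this order (a test asserts it), only the attribution of
removals in the filter report does.

## Clade-wise screening and the MRS

Co-evolution with a query (gold-standard) set is detected by Ward
hierarchical clustering (Euclidean distance — Ward's criterion
presupposes it) of NPP rows, once over all species (pseudo-clade `ALL`)
and once per clade with ≥ 10 species. The threshold is inclusive: ≥ 10
reproduces published clade lists that include 10-species clades.

Because no single flat-cluster resolution is privileged, each dendrogram
is cut at a fixed grid of cluster counts, by default
k ∈ {10, 20, 50, 100, 200, 500} ∩ [2, n−1]. A fixed grid (rather than
dynamic tree cutting) keeps the screen deterministic and lets the maximal
score range over coarse (global) and fine (module-sized) structure.

For gene g in cluster C at one clade/cut, with query set Q:

    ratio(g) = |C ∩ Q \ {g}| / |C \ {g}|   if |C| ≥ min_cluster_size (3), else 0

and MRS(g) is the maximum over all clades and cuts, with the argmax
recorded. The statistic is a **reconstruction**: the published method
names the score and fixes its [0, 1] range but not the formula. The
leave-one-out purity was chosen because (a) it spans [0, 1] exactly,
(b) a gene cannot vouch for itself (a non-query gene surrounded entirely
by query genes scores 1, a query gene does not get credit for its own
membership), and (c) it is monotone in the query set and in the set of
clades, which the property tests assert. `min_cluster_size = 3` exists
solely to kill trivial purity-1 pairs.

Candidates are the top ⌊fraction × n⌋ genes (default 1%, minimum 1) by
MRS, ranked descending with lexicographic gene-id tie-break; query genes
keep their rank but are excluded from the returned candidate list.

## ML validation

The cross-species check asks whether NPP rows predict membership in the
curated set at all. Cleaning follows the 3-sigma rule: per feature,
values strictly outside mean ± 3 sample sd become missing; features and
then samples with strictly more than 20% missing are dropped;
remaining gaps are filled by linear interpolation along each gene row
over the fixed species ordering, with edge gaps taking the nearest
observed value. Interpolating along rows (not columns) is a
reconstruction choice: a gene's profile is the biologically meaningful
series. Cleaning is idempotent on well-behaved data but not by
construction — re-estimating σ after interpolation can in principle
expose new tail values.

Class imbalance (few positives among thousands of genes) is handled by
Cluster-Centroids undersampling: K-means (k = minority count, k-means++
init, tol 1e-6, ≤ 300 iterations, fixed seed) on the majority rows,
which are then replaced by the k centroids; minority rows pass through
byte-identical. Undersampling is applied to the training partition only,
after a stratified 80/20 split (split ratio is a reconstruction; applying
the sampler before splitting would leak test information).

Classifier defaults are the validated optima: MLP with hidden layers
(180, 90, 40), ReLU, Adam, initial learning rate 1e-4, L2 α = 0.1; RF
with 55 trees of max depth 15. A grid-search mode (`param_grid=` in
`train_and_eval`) cross-validates alternatives. Metrics are accuracy,
precision, recall and F1 for the positive class, reported with their
confusion counts. Clade-level importance averages the forest's
impurity-based per-species importances within each clade (SE = sd/√n,
0 for singleton clades, sub-threshold clades omitted).

## Correlation and enrichment

Anchor-gene co-evolution uses Pearson correlation between NPP rows
(appropriate on Z-scored profiles; the observed coefficient distribution
is near-normal), excluding the anchor from its own ranking and applying
the same floor/tie rules as candidate selection to the top percentile.
Term enrichment is the upper-tail hypergeometric test on flat gene→term
annotations (no ontology-graph propagation), adjusted by
Benjamini–Hochberg across all terms present in the universe; the
universe defaults to all annotated genes and is configurable.

## The synthetic generator

`simulate_dataset` emulates exactly the structure the pipeline exploits:

- species are partitioned into clades (default 4 × 12);
- every gene draws one latent conservation mean per clade in
  [0.05, 0.95]; genes of a planted module share those clade means;
- species-level values add Gaussian noise with sd
  `background_noise_sd` (default 0.25) for background genes and
  `background_noise_sd × (1 − signal_strength)` for module genes
  (default signal 0.9), clipped to [0, 1];
- the latent profile maps affinely onto bit-scores between the 24.6-bit
  floor and the gene's self-score (drawn uniformly from (200, 1000), so
  the ≤ 80 self-score filter only triggers when configured);
- a `missing_rate` fraction of entries (default 5%) is deleted — absent
  hits are encoded by omission from the hit tables, matching real
  BLAST-tabular semantics;
- module genes carry a shared annotation term and form the positive
  class for the ML stage; the default query set is the first half of a
  module, leaving the second half as recoverable held-out truth.

The default condition — 2,000 genes, 4 clades × 12 species, one 20-gene
module at signal 0.9 — is the benchmark used by the recovery test and
the acceptance script (20 independent seeds). What the generator does
**not** emulate: real sequence content (FASTA entries are dummy
peptides), correlated missingness, lineage-specific gene families,
phylogenetic autocorrelation within clades, or realistic effect sizes —
published data do not constrain the real co-evolution effect size, so
`signal_strength` is a calibration knob. Passing the synthetic benchmarks
therefore shows the machinery is correct and sensitive under clade-block
structure, not that any particular real screen will reach the same
recall.

## Numerical and degenerate-input choices

- Ward clustering and tree cutting use `scipy.cluster.hierarchy`
  (`linkage`, `cut_tree`); `cut_tree` guarantees exactly k clusters.
  Merge order on exact distance ties follows scipy's conventions;
  continuous data make ties measure-zero.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf`, BH from
  `statsmodels`; the test suite checks both against exhaustive
  enumeration oracles (all merge sequences for ≤ 8 genes; all draws for
  universes ≤ 12).
- Constant NPP columns → zeros + warning; constant profiles get NaN
  correlation and never enter a top set; a constant anchor is an error.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`, scikit-learn `random_state`); identical
  seeds give byte-identical fixtures and identical candidate lists.
- Candidate-count rounding: floor, minimum 1; ties broken by gene id.

## Known limitations

- The MRS formula and the tree-cut grid are reconstructions (above); a
  different published implementation may rank boundary genes
  differently.
- At fine cut levels small clusters can reach purity 1 from as few as
  two query co-members; `min_cluster_size` bounds but does not remove
  this granularity effect.
- Enrichment treats annotations as flat; without DAG propagation,
  parent terms are only enriched if annotated explicitly.
- The ML stage validates signal presence; it is not a calibrated gene
  classifier, and reported metrics depend on the class balance of the
  test partition.
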