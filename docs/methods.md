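# Methods

## The stability model

A gene is *stably expressed* at a given level when the dispersion of its
expression across the units of that level is small relative to its mean.
The index used throughout is

    GESI = 1 / (1 + δ/u)

with u the mean and δ the standard deviation of expression over the
grouping units — resampled bins within a cluster, cluster mean profiles
within a cell type, or cell-type mean profiles within a sample. GESI is
scale-invariant, strictly decreasing in the coefficient of variation
δ/u, equal to 1 at zero variance, and undefined (not 0) when u = 0: a
silent gene carries no stability evidence, and assigning it 0 would turn
absence into an "unstable" call. The cutoff 0.667 used at the
inter-group levels is exactly δ/u < 0.5.

δ is the sample (n−1) standard deviation at every level. Bins are a
sample from the space of possible resamples, so the sample estimator is
the natural choice; at the default r = 100 the distinction is
negligible. At the inter-group levels a standard-error variant (δ/√k)
is available (`use_sem=True`); the default keeps one formula at every
level of the hierarchy.

## Binning

Per-cell UMI counts are dominated by sampling noise. Within each cluster
of ≥ m cells (per sample), r rounds of resampling each draw n distinct
cells and sum their UMI vectors. Sampling within a round is without
replacement — a bin is a set of real, distinct cells — while rounds are
independent, so the r bins are exchangeable draws from the cluster.
Defaults n = 10, m = 100, r = 100.

Bins are depth-normalized to a fixed total (default 10⁴ combined UMIs)
before GESI. Member cells have unequal sequencing depth, and without
normalization the index would conflate depth variance with expression
variance; `normalize=False` restores plain combined counts. Bin totals
of zero are an error rather than silently propagated NaNs.

Reproducibility does not depend on iteration order: each (sample,
cluster) pair derives its own RNG substream from the run seed and CRC32
hashes of the identifiers.

## The hierarchy

1. **Within-cluster SEGs** — the K = 1000 genes with largest GESI across
   bins. Ties at rank K are broken by descending mean expression, then
   gene id: deterministic, and favoring well-measured genes.
2. **Cell-type SEGs** — the within-cluster sets of one cell type are
   intersected by a sharing fraction relaxed greedily down the grid
   100% → 75% → 50% until at least S = 500 candidate genes are retained
   (the grid mirrors the parameter combinations evaluated when the
   thresholds were tuned); candidates must then show inter-cluster
   GESI > g = 0.667 across cluster mean profiles. A single-cluster cell
   type cannot be filtered inter-cluster; its set passes through with a
   `single_cluster` provenance flag.
3. **Sample SEGs** — intersection of the sample's cell-type sets, plus
   inter-cell-type GESI > g. This is the step that deliberately weights
   rare cell types equally with abundant ones.
4. **Tissue SEGs** — genes recurring in ≥ c of the tissue's sample
   sets; c defaults to 2 when the tissue has more than one sample and 1
   otherwise. Recurrence across donors is the guard against
   sample-specific artifacts.
5. **Global (spatial-temporal) SEGs** — genes in ≥ l tissue sets that
   additionally appear in at least one adult *and* one fetal tissue.
   l defaults to 2 and is always recorded; the binding constraint at the
   default is the dual-stage requirement, which is what makes the call
   "spatial-temporal". A relaxed mode (`strict_stage=False`) accepts
   either stage alone for broader, lower-confidence lists.

Monotonicity holds by construction: raising g, c or l can only shrink
the corresponding set; raising K can only grow within-cluster sets; the
strict-stage global set is contained in the relaxed one. Sample SEGs are
subsets of every constituent cell-type set, tissue SEGs of the union of
their samples' sets, global SEGs of the union of tissue sets.

## Specificity and markers

Stage-specific SEGs require presence in ≥ k tissues of one stage and
**zero** tissues of the other (k = 5 for a high-confidence list, k = 2
for enrichment-style analyses). Within a tissue, per-cell-type SEG sets
are aggregated over the tissue's samples with the same ≥ c recurrence
rule as tissue SEGs — the aggregation rule is this package's choice,
made to keep a single recurrence concept — and a cell-specific SEG is a
gene unique to exactly one cell type's set. Marker SEGs are the subset
of cell-specific SEGs with (1) > 2-fold mean elevation in the target
type versus every other type and (2) one-sided Welch's t-test p < 0.05
per comparison, required in **every** analyzed sample of the tissue.
Per-cell values are depth-normalized before testing; a zero mean in a
competing type yields an infinite fold (criterion 1 passes, flagged).
Welch's unequal-variance form is used because single-cell variances
differ strongly between types; no multiple-testing correction is applied
(the criterion is a plain per-comparison p < 0.05), and a stricter alpha
can be passed where a correction is wanted.

## SEGdecon

The signature weight W[s,c] is the average UMI count of cell-specific
SEG s per cell of type c in the training data; the bulk vector E is the
average over all test cells. The unconstrained least-squares solution of
W f = E is computed by QR (`numpy.linalg.lstsq`), with a rank check that
names near-collinear cell types. Because fractions are physical
quantities, the reported default clamps negative components to zero and
renormalizes to sum one; `mode="raw"` reports the literal solution.
Accuracy against known composition is 1 − |real − pred|/real per type
(undefined and excluded at real = 0; negative for gross errors),
averaged over types. `merge_fractions` sums predictions over declared
type groups for annotations that merge hard-to-separate types (e.g. a
combined NK/T label). No normalization is applied to W or E beyond
per-cell averaging; a CPM mode exists for cross-platform signatures.

## Synthetic data

The generator emulates what the caller assumes about droplet data:
negative-binomial (Gamma-Poisson) UMI counts — dispersion `size` = 2 by
default — with log-normal per-cell depth factors (sd 0.3, injected
deliberately so the bin-normalization choice is exercised), organized as
stages × tissues × samples × cell types × clusters. Planted classes:

- **global_seg** (50 of 2,000 by default): one base mean per gene, drawn
  log-normal around 5 UMI/cell (stable reference genes are
  characteristically abundant), identical in every cluster — the CV of
  true means is exactly 0.
- **tissue_seg** (30): constant within one home tissue, drawn
  independently per cluster elsewhere.
- **cell_specific** (40): constant in one target type; in other types
  the mean is unchanged but the counts are strongly overdispersed
  (size = 0.05), so the gene is a SEG only for its target — type
  specificity by instability, not by level.
- **marker** (20): as cell_specific, plus a planted 5-fold elevation in
  the target type.
- **silent** (100): all-zero rows.
- **variable** (remainder): true means drawn independently per cluster,
  log-normal with sdlog 1 (CV of true means ≈ 1.3).

The default scale — 2 stages × 3 tissues × 2 samples × 4 cell types ×
250 cells = 12,000 cells × 2,000 genes — was chosen so a full
simulate-plus-pipeline cycle completes in seconds on one CPU while every
hierarchy level still has work to do; the invariant and determinism test
batteries use a further reduced configuration (300 genes, 2 tissues per
stage, 3 cell types, r = 30, K = 150, S = 80) so they can sweep 20 seeds
cheaply.

What the generator does **not** emulate: batch effects between samples,
ambient RNA, doublets, gene–gene correlation, and the mean–variance
trends of real UMI data beyond the NB family. Consequently, passing
recovery tests demonstrates correctness of the algorithmic chain on its
own model assumptions, not performance on real tissue atlases. One
visible artifact: because variable genes are resampled per cluster yet
remain NB-stable *within* a cluster, some land in exactly one cell
type's SEG set of a tissue and are counted cell-specific; the planted
cell-specific truth is still recovered, but pipeline-derived
cell-specific sets on synthetic data are supersets of the planted ones.

## Numerical and degenerate-input choices

- Silent genes: GESI = NaN everywhere, excluded from candidacy and from
  top-K ranking.
- Empty intermediate sets propagate as empty results with warnings; the
  pipeline never aborts on an empty step.
- A cluster smaller than the bin size n is a precondition error; a
  cluster below m is silently excluded (that is the m filter's job).
- Gene identity is the feature-file ID column; symbols are optional
  metadata (symbols collide).
- Counts are stored genes × cells; both orientations are readable behind
  an explicit flag, never guessed.
- Cells missing cluster or cell-type labels are dropped (logged) before
  any SEG step.
- No mitochondrial/ribosomal pre-filter is applied by default; the
  caller operates on whatever gene universe it is given.
- SEG-set serialization is byte-stable (rank-explicit TSVs, sorted JSON
  keys, no timestamps in set files), which is what makes the
  determinism contract testable at the byte level.

## Known limitations

- The number of global SEGs depends on tissue/sample coverage and on l;
  with few tissues the dual-stage requirement dominates.
- GESI is most informative for moderately-to-highly expressed genes:
  low-mean genes have large sampling CVs in bins of 10 cells and rarely
  enter the top-K, so lowly expressed stable genes are under-called.
- The marker screen tests mean elevation only; a bimodal gene can pass
  in an average sense.
- SEGdecon assumes the signature types span the test sample; fractions
  of unrepresented types are absorbed into the represented ones.
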