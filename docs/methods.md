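# Methods

This note documents the statistical procedures implemented in
`lsec_sigkit`, the defaults and the reasoning behind them, what the
synthetic data emulate, and the limits of what the test suite demonstrates.

## Marker testing (`differential_expression`)

Two cell groups are compared per gene with a two-sided Wilcoxon rank-sum
test on log1p CP10K-normalized expression. For pooled samples of at most 16
tie-free observations the exact permutation distribution is used
(`scipy.stats.mannwhitneyu(method="exact")`, verified in the tests against
full enumeration); otherwise the normal approximation with midranks,
tie-corrected variance and continuity correction. Rows whose pooled values
are constant get p = 1.

The effect size is a **linear fold change on de-logged means**:
fc = (mean expm1(focal) + ε) / (mean expm1(ref) + ε), ε = 1e-9. The ε keeps
all-zero groups finite; an all-zero focal group against a detected
reference yields fc ≈ 5e-10 rather than an error. Detection is quantified
as the fraction of cells with raw count > 0 (`pct`), always computed on raw
counts (normalization preserves zero/nonzero status, which the tests
assert).

A gene is *flagged as a marker* when all three hold:

* fc strictly greater than `min_fc` (default 2 — "larger than" is a strict
  inequality, so fc = 2.0 exactly is not a marker);
* `pct_focal ≥ min_pct_focal` (0 by default; the derivation stage sets 0.5);
* Benjamini–Hochberg q ≤ `max_q` (default 0.05). The BH step-up runs over
  the genes actually tested in the contrast.

Only genes detected in at least `min_detect` (default 0.1) of either group
are tested; set `min_detect=0` to test everything. The default bounds
compute and avoids reporting p-values for genes whose rank distribution is
almost entirely ties.

Calibration: on a null simulation the per-gene rejection rate at p < 0.05
is ≈ 0.05 on average, but the *aggregate* fraction for one dataset has a
standard deviation of roughly 0.007 rather than the binomial ≈ 0.005,
because shared per-cell library-size factors couple genes within a cell:
a chance depth imbalance between the groups shifts every gene's zero
fraction in the same direction. Single-seed aggregate fractions in the
0.039–0.059 range are therefore expected and do not indicate miscalibration
of the per-gene test.

## Staged signature derivation (`signature_derivation`)

Cell groups are addressed by (population, condition) selectors. The stages:

1. **`enriched_vs_all_types`** — markers of the focal population against
   *each* other population separately; the result is the intersection of
   the flagged sets, further restricted to genes detected in ≥ `pct_min`
   (default 0.5) of focal cells. A pooled-reference mode
   (`comparison_mode="one_vs_pooled"`) is provided because the one-vs-each
   and one-vs-pooled readings of "enriched against all other cell types"
   genuinely differ; one-vs-each is the default as it is the stricter
   criterion and matches how per-population upset plots are built.
2. **`condition_contrast`** — markers of healthy LSECs vs the damaged
   LSEC/EC population and vice versa (no detection-fraction filter); the
   two sets are disjoint by construction.
3. **`build_state_genesets`** — per-state sets as the intersection of (1)
   and (2).
4. **`refine_damaged_signature`** — the damaged state set restricted to
   genes also up (fold > 2, significant) against healthy endothelial
   cells. This removes generic endothelial genes that the within-cirrhotic
   enrichment cannot see, leaving the compact damaged-LSEC signature.
5. **`concordance_filter`** — keeps genes whose mean bulk difference
   (group 2 − group 1) has a required sign; matching is case-insensitive so
   human signatures apply to mouse-style symbols. Genes absent from the
   bulk matrix are dropped and listed in provenance. The sign-of-difference
   rule is deliberately simple: the selection it models is qualitative
   (which genes fall after injury), and any threshold sharper than the sign
   would demand effect-size calibration across platforms.

**Condition scoping.** Population enrichment is computed within the
condition the state belongs to: the healthy-LSEC set against the other
healthy-liver populations, the damaged set against the other
cirrhotic-liver populations. Cross-condition information enters through the
condition contrast (stage 2) and the refinement against healthy ECs
(stage 4). Running the damaged enrichment against a pooled
healthy-plus-cirrhotic EC population would pre-empt stage 4 — a gene shared
with healthy ECs could never pass a two-fold test against the pooled EC
cluster, and the refinement step would have nothing to do; the per-condition
scoping keeps the two filters distinct, which is also how the staged
procedure is presented in the field.

Every derived `GeneSet` carries a `provenance` trail of the thresholds,
populations and intermediate set sizes that produced it.
`intersection_summary` reports exact exclusive (upset-style) membership
counts; the counts always sum to the size of the union.

## Module scoring (`signature_scoring`)

The score of cell *c* for signature *S* is

    score(c) = mean_{g in S} x(g, c) − mean_{g' in C} x(g', c)

where *x* is normalized expression and *C* is the control pool: genes are
ranked by dataset-wide mean expression and cut into `n_bins` (default 24)
equal-frequency bins (sizes differ by at most one; ties broken by stable
gene order), and for each signature gene `n_ctrl` (default 100) controls
are drawn with replacement from its bin, excluding all signature genes.
Controls are drawn **once per (matrix, signature, seed)**, not per cell, so
scores are comparable across cells and deterministic. The control pool is a
multiset — genes drawn twice count twice. If a bin contains no
non-signature gene the pool falls back to all non-signature genes.

Means are computed as explicit sums divided by counts rather than via
sparse-matrix `.mean`, so a constant matrix scores exactly zero (the
sparse mean multiplies by a rounded 1/n and leaves ~1e-15 residues).

Consequences asserted in the tests: adding a constant to all genes of a
cell leaves that cell's score unchanged; a random signature scores ≈ 0 in
every population; the planted case-study signatures separate their target
populations with AUC > 0.99 (rank-based Mann–Whitney AUC against all other
cells).

The defaults (24 bins, 100 controls) follow the widely used single-cell
scoring convention; both are exposed because the verbal definition of the
score does not fix them.

## Bulk enrichment (`enrichment_gsea`)

Genes are ranked by signal-to-noise: (μ₁ − μ₂)/(σ₁ + σ₂) with each sample
standard deviation (ddof = 1) floored at max(0.2·|μ|, 0.2) — the classic
adjustment that stops near-constant genes from dominating. Ties in the
metric are broken by gene symbol so the ranking is reproducible.
`positive_group` selects which group occupies the positive end.

The enrichment score of a set of k genes in a ranked list of N is the
extremum (first occurrence on ties) of a running sum that gains
|metric|^p / Σ_hits |metric|^p at member genes (weight p = 1 by default)
and loses 1/(N − k) at non-members; |ES| ≤ 1, and the final value is
clipped to [−1, 1] to absorb cumulative-sum float drift. If all hit weights
are zero (a completely flat metric) hit mass falls back to uniform. The
leading edge is the members at or before (positive ES) / after (negative
ES) the extremum.

Null distributions: **phenotype** permutation relabels samples and
recomputes the full ranking per permutation (default when both groups have
≥ 7 samples); **gene_set** permutation resamples random same-size index
sets against the observed ranking (default for smaller groups).
NES = ES / mean(|null ES| of the same sign); the nominal p is the same-sign
tail frequency with an add-one correction; the FDR q follows the classic
pooled NES tail-ratio estimator (fraction of pooled null NES at least as
extreme, divided by the fraction of observed NES at least as extreme),
clipped to [0, 1]. Reported sets are filtered with |NES| > 1 and
FDR < 0.25.

Two validation scenarios deserve comment. (i) *Calibration*: with a null
bulk matrix and 2,000 random sets under gene-set permutation, the nominal-p
rejection rate at α = 0.05 is ≈ 0.045 (the add-one correction makes it
slightly conservative). (ii) *Power*: with a 50-gene set shifted +2 log2
units in one group, the planted set reaches NES ≈ 2.4 with q ≈ 0 under
gene-set permutation while ≥ 95 % of random decoy sets fail the reporting
filter. The power check uses the gene-set null deliberately: when one true
set is tested alongside dozens of decoys, the pooled-FDR estimator under
phenotype permutation correctly dilutes the true set's q toward the
fraction of tested sets that are null (q ≈ 0.33 in this scenario) — that is
a property of FDR among a almost-all-null collection, not an
implementation defect. Decoy sets are drawn uniformly from all genes; sets
built to avoid the planted genes are systematically *anti*-enriched
(the planted mass occupies the top ranks) and a few percent of them pass
the filter on the negative side.

## Synthetic data (`synthetic_data`)

Single-cell counts are negative binomial: gene g in cell c has mean
baseline_g · fold(g, population(c)) · sf_c with dispersion r (default 2;
var = μ + μ²/r). Baselines are log-normal (default median 1, σ_log = 1),
size factors log-normal with σ = 0.2. Markers are planted by multiplying
the mean by a fold change within a population (optionally restricted to a
condition). Detection fractions follow implicitly as
1 − NB(0; μ, r) — there is no separate dropout layer, which keeps the
ground-truth pct analytically computable. `baseline_means` lets two
datasets share one baseline vector (the case study's healthy and cirrhotic
livers describe the same gene space, so baseline expression must not differ
by condition), and `baseline_mean_override` pins planted genes to a known
moderate baseline (1.0) so that a fold change of 8 puts them at ≈ 96 %
detection in the focal population and ≈ 44 % elsewhere — the regime the
≥ 50 %-detection filter is meant to discriminate.

Bulk values are log2-scale: per-gene log-normal baseline + planted group-2
shifts + Gaussian noise (σ = 0.25 by default, 8 samples per group in the
case study).

The default **case study** (2,000 genes, 300 cells per population, fold
change 8) plants: 30 LSEC markers (both conditions); 4 damaged-specific
genes in the cirrhotic-only damaged population; 6 endothelial genes shared
between the damaged population and healthy-condition ECs (enriched within
cirrhotic livers, removed by the refinement stage); and bulk shifts of −2
log2 for 12 LSEC markers ("injury-down", the intended restricted healthy
signature) and +1 for the other 18 (genes that rise after acute injury and
must be excluded). Familiar liver-endothelial gene symbols are used for the
planted genes purely for readability — all data behind them are simulated.

What the simulator does **not** emulate: ambient RNA, doublets, batch or
chemistry effects, mean-variance trends beyond the single dispersion
parameter, gene-gene correlation beyond shared library size, or the
compositional coupling of real cell types. Passing the planted-truth tests
therefore demonstrates that the pipeline's logic and statistics are
correct, not that the thresholds are optimal for any particular real
dataset.

## Numerical and interface choices

* Normalization: log1p of counts per 10,000 (natural log); per-cell
  Σ expm1(value) equals the scale factor to ~1e-6 relative. Cells with zero
  totals must be filtered first (`filter_cells_genes`, defaults 200
  counts/cell and 3 cells/gene; cells are filtered before genes).
* Bulk normalization: log2(1 + CPM) or pass-through for already-normalized
  tables.
* Gene symbols are uppercased inside `GeneSet` only; matrices keep their
  case, and all matrix↔set matching is case-insensitive (mouse Fabp4
  matches human FABP4). Orthology beyond symbol case-folding is out of
  scope and noted in provenance.
* MatrixMarket orientation is inferred from label-file lengths; an
  ambiguous square matrix is assumed genes × cells with a logged warning,
  and the total count is asserted unchanged by any transpose.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec/params objects; the CLI derives per-stage streams from one
  global seed and writes a manifest (no timestamps) with sha256 checksums,
  so reruns are byte-identical.
* Problem sizes in the test suite (2,000 genes, ≤ 2,700 cells, ≤ 2,000
  permutations/sets) were chosen so the full validation runs in about half
  a minute while keeping every planted effect in the regime the thresholds
  target.

## Known limitations

* The Wilcoxon asymptotic path is slightly conservative for very sparse
  genes (heavily tied ranks); the `min_detect` prefilter avoids the worst
  of it but aggregate rejection rates on discrete data sit a few percent
  below nominal.
* The damaged-signature refinement assumes a healthy endothelial reference
  population exists and is labeled; without it the refined signature is
  undefined (the function then errors or warns on empty results).
* Phenotype permutation with fewer than ~7 samples per group has too few
  distinct relabelings for stable tail estimates; the implementation
  switches to the gene-set null by default in that regime.
* The concordance filter uses only the sign of the bulk group difference;
  genes with near-zero differences are classified by noise. Planting
  clearly signed shifts is essential when validating against ground truth.
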