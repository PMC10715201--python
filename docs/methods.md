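# Methods

This note documents the models and procedures implemented in `dotx`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic generators do and do not emulate.

## Coverage-based sex-linkage classification

**Model.** In an XO male every X-linked position is hemizygous, so the
expected male:female depth ratio is 1/2 on the X and 1 on autosomes (after
library-size correction). Y-linked sequence, if present, has male coverage
but essentially no female coverage.

**Procedure and defaults.**

- Windows are 10,000 bp, 0-based half-open (BED convention); the last window
  of a scaffold may be shorter. Per-base depth tables are binned by summing
  reported depths over the full window span, so unreported positions count as
  depth 0.
- Each sex's window depths are divided by that sex's genome-wide *median*
  window depth. The ratio statistic is then library-size free, which is what
  makes a fixed δ = 0.5 offset meaningful when male and female libraries
  differ in depth. The median (not the mean) is used so X windows and
  coverage outliers do not drag the autosomal anchor.
- Per window, log2((M + c)/(F + c)) with pseudocount c = 0.1 in normalized
  units. Windows where *both* raw depths are below 3 reads are masked:
  ratios of noise against noise are sign-random and would otherwise dominate
  small scaffolds. Windows where only one sex is near zero are deliberately
  kept — that asymmetry is the Y signature.
- Cutoff: median of all unmasked window ratios minus δ (default 0.5, i.e.
  ~1.4-fold below the autosomal mode, half way to the 2-fold X expectation
  on the log2 scale). A scaffold is X-linked iff its per-scaffold median
  ratio is strictly below the cutoff. Scaffolds with fewer than 5 usable
  windows are reported `unassigned` rather than forced into a class.
- Median of an even number of windows is the mean of the two central values
  (numpy convention).
- Male-specific screen (raw depths): median female depth ≤ 1 read and median
  male depth ≥ 5 reads. Both comparisons are inclusive and applied to raw,
  not normalized, depth.

The classifier is shift-invariant (the cutoff is median-relative) and
invariant to rescaling either sex's depths (absorbed by the normalization);
both properties are regression-tested.

## Ortholog homology and enrichment

- Hit filtering keeps scores strictly above 50, then one best-scoring hit per
  query (ties broken deterministically by (target, start) with a warning),
  then resolves placements on a common target that overlap by more than 20 bp
  in favour of the higher score; an overlap of exactly 20 bp keeps both.
  Placements are processed in descending score order with lexicographic query
  tie-breaks, making the retained set idempotent and independent of input row
  order. Overlap is computed on genome coordinates ignoring strand.
- The *X-linkage threshold* is the global proportion of orthologs X-linked in
  the focal species. Per-element enrichment uses the 2×2 table
  {element vs rest} × {X vs not} with Yates continuity correction
  (`scipy.stats.chi2_contingency`). An element is *overrepresented* when its
  raw p < 0.05 **and** its proportion exceeds the threshold; BH-adjusted
  p-values are reported alongside, but the flag uses the raw rule.
  Degenerate tables (a zero margin) carry no information and score (0, 1).
- The partition analysis groups focal X genes by whether their outgroup-1
  homolog is on element F, and tests each group against the autosomal
  background for X-linkage in outgroup 2 (Yates chi-squared, BH across the
  two comparisons). Groups with fewer than 2 genes report a proportion but
  skip the test.

## Expression pipeline

- Quantile normalization maps every column onto the across-column mean of
  sorted values; tied values receive the mean of the reference values spanned
  by their ranks, so output columns share an identical value multiset and the
  transform is row-order invariant.
- Dosage procedure per tissue: normalize the tissue's samples, average within
  sex, quantile-normalize the two sex averages (removing any residual global
  shift between sexes), keep genes strictly above 0.5 TPM in both sexes.
  Three Wilcoxon rank-sum contrasts are reported (X male vs X female, X male
  vs autosomal male, per-gene log2(M/F) on X vs autosomes), BH-adjusted.
  Rank-sum tests use the exact null for tie-free samples of ≤ 20, otherwise
  the normal approximation with continuity correction.
- Sex-biased genes: the differential test is a Welch t-test on
  log2(TPM + 0.5) across replicates of the quantile-normalized tissue
  samples. This is a deliberate design choice over bootstrap-based
  quantification-uncertainty models: it needs only the abundance matrix,
  is exactly reproducible, and feeds the same decision thresholds (BH
  q < 0.05, both sex means > 0.5 TPM, fold-change ≥ 2 on the normalized sex
  means). The 0.5 offset in the log transform matches the expression floor.
  Genes with zero variance and equal means get p = 1 rather than NaN.
- Tissue-specificity contexts are head, carcass, ovary (female gonad) and
  testis (male gonad); a gene is specific where it exceeds 1 TPM while below
  0.5 TPM in all other contexts. Because 1 > 0.5 at most one context can
  ever qualify.
- X-vs-autosome proportion comparisons decline the chi-squared when any
  expected cell count is below 5 and report the table descriptively instead;
  with very few called genes the test statistic is not meaningful.

## Landscape metrics

- GC per window is (G+C)/(A+C+G+T); Ns reduce the denominator and an all-N
  window is masked. Case-insensitive, reverse-complement invariant.
- Repeat density is the fraction of window bases covered by the *union* of
  annotations (never > 1 under stacked annotations). Annotations beyond the
  scaffold end are clipped with a warning. RepeatMasker class strings map to
  coarse classes: families containing "DNA" are DNA transposons;
  LINE/SINE/LTR are retrotransposons; everything else is "other".
- π uses per-site allele counts: contribution k(n−k)/C(n,2) for a site with
  n ≥ 2 genotyped alleles and k alternates; a window's value is the mean
  contribution over its genotyped sites, and windows with none are masked.
  Missing genotypes reduce n at that site rather than removing the site, and
  sites absent from the input are *not* assumed invariant — the caller must
  supply invariant sites (e.g. from an all-sites VCF) for the denominator to
  be correct. Default windows: 28 kb for π (roughly one value per long
  transcript when computed on transcriptome alignments), 10 kb for GC and
  repeats. Note that π computed from RNA-seq-derived genotypes can be biased
  by allele-specific expression; the estimator is implemented as defined and
  does not model this.

## Neutral Wright-Fisher coalescent

Pairwise coalescence times are sampled by explicit backwards
generation-by-generation parent sampling — not the exponential
approximation — so the X/A prediction is an output of the copy-number
bookkeeping. Autosomal lineages pick a parent of either sex with probability
1/2 and one of its two copies; X lineages in a male go to the mother (an XO
male's X is always maternal), in a female to mother or father with
probability 1/2, a father contributing his single copy. Two lineages
coalesce when they select the same parental copy. Per locus π = 2µT. With
n_m = n_f the expected ratio of means is 3/4; with unequal sexes it follows
N_e(X)/N_e(A) = [9 n_m n_f/(4 n_m + 2 n_f)] / [4 n_m n_f/(n_m + n_f)], which
the tests verify at a 20:80 sex ratio. The default acceptance run uses 500
males + 500 females, µ = 1e-8 and 10,000 loci per compartment, where the
Monte-Carlo standard error of the ratio is ≈ 0.011; the simulation is
vectorized over loci and completes in seconds on one CPU.

An all-female configuration is rejected: without males the X and autosomal
copy numbers coincide and the contrast is undefined.

## Synthetic data: what it emulates, and what it does not

The generators produce data whose *statistical structure* matches the
analysis assumptions, each paired with a truth table:

- Genome: 25 scaffolds by default with 8% X-linked (2 scaffolds), lengths
  100–250 kb so each carries ≥ 10 windows; optional Y-like scaffolds and one
  default "confounder" scaffold whose coverage varies in both sexes through a
  shared log-normal factor (σ = 0.6) — variable depth with a balanced M:F
  ratio, a known failure mode for naive classifiers that the suite
  regression-tests.
- Coverage: Poisson window counts by default (clean analytic means); a
  negative-binomial option (variance m + 0.05 m²) reflects the
  overdispersion of real libraries. Mean depth 30 is a testability choice —
  deep enough that classifier errors indicate bugs, not noise. Y-like
  scaffolds get a residual female rate of 0.02·D emulating cross-mapping.
- Expression: 3 replicates × 2 sexes × 3 tissues (18 libraries); per-gene
  baselines log-uniform on [0.1, 1000] TPM (heavy-tailed, as TPM is), with
  log-normal noise σ = 0.1. Sex-biased genes (10%, 4-fold, balanced
  directions, gonad only) draw baselines above 2 TPM so every truth label is
  detectable in principle; tissue-specific genes (10%) sit at 20 TPM in the
  focal context and 0.05 elsewhere. The default dosage pattern is
  compensated soma + uncompensated gonad (male X means halved). Columns are
  not re-normalized to sum 10⁶: renormalization would distort the configured
  fold-changes, and the analysis path quantile-normalizes anyway.
- Landscape: Gaussian GC (base 0.40, sd 0.02, X shift −0.05), Gaussian repeat
  fraction (base 0.30, X shift +0.05), gamma-distributed π (shape 2) with an
  X/A mean ratio of 0.23.

Not emulated: read-level artifacts (mappability, GC bias, duplicates),
linked selection, real repeat sequence models, quantification uncertainty,
and correlation structure along chromosomes (windows are independent draws).
Passing tests therefore demonstrate correctness of the estimators and
decision rules under the stated sampling models — not robustness to
alignment or assembly pathologies, which are out of scope.

## Determinism and problem sizes

All generators draw from seed-derived independent streams (fixed spawn keys
per data type), so a configuration is bit-reproducible and generating one
data type never perturbs another. Stochastic checks in the test suite either
fix a seed chosen up front or aggregate over many seeds (100 classifier
replicates; 200–500 replicates for the calibration checks); problem sizes
(e.g. 300–2,000 genes, 10,000 coalescent loci) were chosen so the whole suite
runs in well under a minute while keeping Monte-Carlo error far inside the
asserted tolerances.
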