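# Methods

This note documents the models, estimators and numerical choices behind
`lofscreen`, and what the synthetic-data generator does and does not
emulate.

## Gene-set construction

A gene-level table carries, per gene, the aggregate mean allele frequency
(MAF) of its predicted loss-of-function variants, plus coding and
misannotation flags. The set keeps genes with MAF **strictly** greater than
the threshold (default 0.001, i.e. 0.1%) that are coding and not
misannotated. Because a gene can fail several filters at once, drop
accounting uses a fixed precedence — misannotated, then non-coding, then
MAF — so the three counts are disjoint and sum with the output size to the
input size. Duplicated symbols and MAF values outside [0, 1] are errors that
name the offending records.

Consequence classification treats `stop_gained`, `frameshift_variant`,
`splice_donor_variant` and `splice_acceptor_variant` as LoF,
case-insensitively; unknown terms classify as non-LoF (real catalogs carry
vocabulary this list does not) and are tallied rather than rejected.
Consequence-composition comparisons report
`100·(f_in − f_out)/f_out` per term; a term never seen outside the set has
no defined denominator and is flagged `undefined` rather than mapped to
infinity.

## GWAS trait enrichment

Preprocessing: unmapped SNPs are assigned to the nearest same-chromosome
gene, with distance 0 inside the 0-based half-open interval and otherwise
the distance to the nearer edge, `min(|pos − start|, |pos − (end−1)|)`; ties
break by smaller start then lexicographic symbol, making results independent
of input order. Traits standardize to the mapped-trait field with the
disease-trait string as fallback. Exclusion filters run in one ordered pass
(studies with >10 distinct traits, studies with >1,000 distinct genes,
traits with <5 distinct genes computed after the first two); no fixpoint
iteration is attempted, so a trait dropping below 5 genes *because* a study
was removed is still excluded, but no second round follows.

The statistic counts unique (gene, trait) pairs among intragenic LoF
associations. The null draws `n_perm` (default 1,000) gene sets, without
replacement, of size `|set ∩ catalog genes|` from the catalog's intragenic
gene universe — size-matching to the set's *footprint in the catalog*
rather than its nominal size, since genes outside the catalog cannot
produce hits. Random sets are not matched on gene length or chromosome;
the generator's associations are placement-neutral, so unmatched uniform
sampling is the correct null there, and matched sampling on real catalogs is
an acknowledged extension. `z = (observed − mean)/sd` with the sample SD
over permutations; `sd = 0` yields an undefined z (excluded from the BH
family), never ±∞. The canonical p is the two-sided normal tail of z — the
permutation count distribution is a sum of hundreds of near-independent
gene indicators, so the normal approximation is accurate at the default
scales — with an empirical rank p available
(`(1 + #{|null − mean| ≥ |obs − mean|})/(n_perm + 1)`) for small universes.
Reporting keeps traits with ≥5 observed hits and |z| > 2.

The PheWAS analogue works per cohort on significant association rows
(deduplicated phenotype–gene pairs). The resampling unit is the association
row, matched in count to the observed set-gene rows; category proportions
are recomputed per draw. Because the statistic is compositional (proportions
sum to 1), enriching one category necessarily depresses the others — an
over-represented category can drag its complements below z = −2. BH runs
within each cohort; cohorts are processed independently of their order in
the input.

## Library design and representation QC

Each of the two sets carries one targeting guide per gene, non-targeting
controls (default 100) and safe-harbor guides (default 5, alternating
between two synthetic safe-harbor site labels). Sequences are unique random
20-mers over ACGT by rejection sampling; on/off-target scoring is out of
scope, so guide "quality" is not modeled.

QC reports Pearson r on raw aligned counts (a log1p option exists; raw is
canonical since the comparison targets representation, not variance
stabilization), percentiles by linear interpolation between order
statistics (stated explicitly because percentile conventions differ across
implementations), and the P90/P10 ratio against the six-fold acceptance
bound. A zero P10 is floored at one pseudocount and flagged. The cumulative
curve gives the read fraction carried by the bottom x fraction of guides.

## Screen quantification and depletion testing

Quantification is exact 20-mer matching (at a fixed offset, or scanning the
read; first hit counted). The generator emits error-free reads, so exact
matching is the correct inverse; no mismatch tolerance is implemented.

Size factors are median-of-ratios restricted to the safe-harbor guides:
reference = per-guide geometric mean across samples (guides with any zero
excluded), factor = per-sample median of count/reference, reported
unscaled. Safe-harbor-only normalization is preferred over all-guide
normalization because genuine widespread depletion would otherwise be
absorbed into the factors.

The depletion test is a two-group negative-binomial model per guide:
`E[k_s] = q·c_s·exp(β·x_s)`, `Var = μ + αμ²`. With a shared α within a
guide, the MLE of β is the log ratio of size-factor-scaled arm means, which
is used directly; `se` comes from the information at the fitted means,
`se² = 1/Σ_base w_s + 1/Σ_tp w_s` with `w_s = μ̂_s/(1 + αμ̂_s)`; the Wald
statistic is referred to the two-sided normal tail and BH-adjusted per
contrast. Arms with zero totals get a 0.5 pseudocount on both arm totals;
guides absent everywhere are flagged untestable and excluded from the BH
family. In the α → 0 limit the statistic reduces to the familiar Poisson
log-ratio test and agrees with the exact conditional-binomial test (raw p
within ~10% at moderate effects and large counts; at extreme significance
the two agree on the equivalent-normal-quantile scale, where p-values many
orders of magnitude below 1 are meaningfully compared).

**Dispersion.** α is estimated per guide by method of moments on scaled
counts pooled across both arms (df = n₀+n₁−2, size-factor-corrected,
clipped at 0) and then **moderated toward the across-guide median** with
prior weight `dispersion_prior_df` (default 20), floored at 1e-8. The
moderation exists because with 3 vs 4 samples the raw per-guide estimate
has ~5 df: plugging it into a normal-referenced Wald statistic produces
t₅-like tails and a null type-I error near 0.10 at nominal 0.05. Pooling
strength across guides restores calibration (measured type-I ≈ 0.065–0.07);
this is a single global shrinkage target, not a fitted mean–dispersion
trend. `dispersion_prior_df=0` recovers the raw per-guide estimator. The
residual mild inflation (~0.065 vs 0.05) is the finite-sample skew of the
log-ratio itself and persists even with the true α plugged in.

Gene-level calls: significant if any guide's padj < 0.05 (each gene has two
guides across the sets). Essentiality uses the minimum-padj guide's log2FC
per contrast (a mean-of-guides aggregate is available) and requires
log2FC < 0 at T7 and T14, |log2FC_T14| > |log2FC_T7| (depletion magnitude
growing — the depletion-context reading of "increasing"), and padj < 0.05
in both contrasts.

Sample QC runs PCA (scikit-learn) on log1p of size-factor-scaled counts
with samples as observations; a constant matrix returns zero coordinates
and zero explained variance rather than erroring.

## Synthetic-data generator

The generator emulates, with the statistical structure the analyses assume:
a gene universe with non-overlapping 0-based half-open intervals on
synthetic chromosomes, above/below-threshold aggregate MAFs and optional
misannotation flags; a GWAS-catalog-style table with per-(trait, gene)
Bernoulli associations (rate 0.1 by default), an enrichment multiplier for
designated traits, intragenic SNP placement, a LoF/non-LoF consequence
mixture (50/50), and fractions of rows lacking the mapped gene (10%) or
mapped trait (5%); per-cohort PheWAS tables with category-level enrichment
(4 cohorts, 500 phenotypes over 10 categories); and screen counts with
lognormal baseline abundances (median 500, log-sd 0.5 — chosen so a clean
library's P90/P10 ratio sits near 4, under the six-fold bound), NB noise
(variance μ + αμ², default α = 0.05, α = 0 degenerating to Poisson), and
geometric depletion of spiked essential genes
(`depletion_per_doubling^doublings`, default 0.8 per doubling at 7 and 14
doublings). The sample layout defaults to three baseline and four
time-course replicates per timepoint. All outputs are byte-deterministic in
(config, seed), with independent substreams per generator.

Deliberately **not** modeled: sequencing error and PCR jackpots (reads are
exact guide sequences with fixed flanks), linkage disequilibrium and
population structure, gene-length- or chromosome-dependent association
rates, trait ontology structure, cross-cohort heterogeneity, guide-efficacy
variation, and copy-number effects. Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated generative model,
not robustness to those real-data pathologies; on real catalogs and screens
the preprocessing assumptions (e.g. exact-match quantification,
misannotation flags supplied upstream) must hold or be handled before
entry.

## Problem sizes and defaults

The test suite and the acceptance script run the permutation calibration at
200 traits × 2,000 genes × 1,000 permutations, the NB null calibration at
3 × 2,000 guides (7 samples each), and the spike-in recovery at the full
two-set library over a 1,551-gene set with 20 essential genes across 10
simulated screens — sizes at which the calibration bands quoted above are
statistically meaningful while a full run completes in seconds. Acceptance
sub-checks that interrogate estimator *accuracy* rather than the study
design use fixtures sized for informativeness: size-factor recovery uses 50
safe-harbor guides because the median-of-ratios sampling error with only 10
controls (~9% at dispersion 0.05) would swamp a 10% accuracy check, and
control-neutrality checks average over all 210 control guides for the same
reason.

## Known limitations

- The nearest-gene assignment is brute-force per chromosome; adequate at
  synthetic scale, but an interval tree would be preferable for
  genome-scale catalogs.
- The NB test assumes a shared dispersion within a guide across arms and
  estimates one α per guide; condition-specific dispersions are not
  modeled.
- Catalog exclusion filters are single-pass by design; iterating them to a
  fixpoint would remove slightly more rows.
- The empirical permutation p is bounded below by 1/(n_perm+1); the normal
  p is used wherever tail resolution matters.
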