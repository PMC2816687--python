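# Methods

This note documents the statistical procedures `hzscan` implements, the
modelling assumptions behind them, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The unit of input is a per-locus multiple sequence alignment of population
haplotypes (two named haplotype sequences per diploid individual, as
produced by phasing workflows), plus a sample table (individual →
population, comparison, phenotype score, haplotype names) and a locus table
(locus → region label, genomic offset). Alignment columns are 0-based
internally and 1-based in every output; the global position of a column is
`genomic_offset + column` (1-based), putting all placed loci on one shared
coordinate axis so inter-locus distances are meaningful.

Haplotype pairing comes from the sample table, not from name suffixes
(a convenience mode infers `_a`/`_b` pairs when the columns are absent):
explicit mapping is unambiguous where phased-output naming conventions are
not. Individuals missing one or both haplotypes at a locus are excluded
from that locus only, with a logged count — sequencing failures are a
per-locus, not per-individual, phenomenon. Individuals with missing
phenotype are retained for diversity and LD statistics and dropped only
from association testing, which maximizes data use per statistic.

## Variant sites and dosage

Columns containing any gap character are excluded wholesale before any
statistic: indel-bearing regions are treated as trimmed, which avoids the
ambiguity of scoring alignment gaps as a fifth state. `N` is a missing
call. A column is a variant site iff at least two distinct non-missing
bases are each observed at least once.

Multi-allelic sites are condensed to two allele classes. When the rarest
allele is below the minor-allele-frequency threshold (default 0.05) this is
ordinary rare-minor merging; when all minor alleles are common the site is
still condensed major-vs-rest but flagged (`all_minors_common`) so users
can exclude such sites — keeping one dosage axis per site is worth the
flag. Site frequencies are computed as count ratios, not `1 − p`, so sites
at exactly the threshold compare predictably; the informativeness filter is
strict (`maf > 0.05`). At a 50/50 frequency tie, the alphabetically later
allele is labelled minor (deterministic, documented, otherwise arbitrary).

Genotype dosage is (copies of non-major allele)/2, i.e. 0, 0.5 or 1,
deliberately on the same scale as the phenotype score. If exactly one of an
individual's two haplotype calls is missing, the genotype is missing — a
half-observed genotype cannot be assigned a dosage without an imputation
model, which is out of scope.

## Diversity and neutrality

π is the mean over haplotype pairs of per-pair per-bp differences, with
pairwise deletion: columns where either sequence is N are dropped for that
pair and the pair's count is normalized by its own comparable length.
Column-wise deletion would discard far too much data under scattered
missingness. No multiple-hit (Jukes–Cantor) correction is applied — at
within-species divergences the correction is negligible and omitting it
matches standard resequencing practice.

Tajima's D uses the classical constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
and is undefined (NA) for S = 0 or n < 4, where the variance terms
degenerate. Its significance is assessed with the beta approximation: D is
assumed to follow a beta distribution rescaled to the support
[D_min, D_max], where D_min = (2/n − 1/a₁)/√e₂ corresponds to every site a
singleton and D_max = (q − 1/a₁)/√e₂ with q = n/(2(n−1)) for even n and
(n+1)/(2n) for odd n to every site maximally balanced (the large-S range of
the statistic). Shape parameters are moment-matched so the distribution has
mean 0 and variance 1 on that support; the two-tailed p is
2·min(F(D), 1−F(D)). D outside the support by more than 1e-9 is clamped
with a warning. The approximation is known to be approximate: on neutral
coalescent samples (n=10, θ=5) the test suite verifies a rejection rate in
[0.02, 0.09] at α = 0.05, not exactly 0.05.

## Hudson's F_ST

F_ST = 1 − H_w/H_b with H_w the unweighted mean of the two
within-population mean-pairwise-difference values (a weighted option
exists; unweighted is the common default when sample sizes are similar) and
H_b the mean over all cross-population pairs. The estimate is reported
unclamped; small negative values are expected sampling noise. Two
small-sample properties worth knowing, both asserted exactly in the tests:
for literally identical population multisets the estimate is
1 − n/(n−1) < 0, because H_w excludes self-pairs while H_b does not; and
duplicating every haplotype shrinks H_w by exactly (2n−2)/(2n−1). Both
effects vanish as O(1/n). H_b = 0 yields NA.

## Association scan

The per-site statistic is the Armitage trend test in score form,
χ² = n·r², with r the Pearson correlation of dosage and phenotype over
pairwise-complete individuals, referred to χ²₁. The (n−1)·r² variant
differs negligibly and is not offered. The statistic is invariant to affine
recoding of either axis (0/0.5/1 vs 0/1/2, allele orientation), and for
binary dosage and phenotype it equals the 2×2 Pearson chi-square — both are
test-suite oracles. Monomorphic sites return NA with a reason, never an
error: scans over thousands of sites must not crash on degenerate columns.

Multiple testing uses Bonferroni on the −log10 scale with a strict `>`
cutoff. The denominator is the number of testable sites in the scan, or a
caller-supplied joint total (e.g. 866) when several scans are corrected
together.

One calibration subtlety, verified by direct simulation in the test suite:
with 30 individuals per group the trend statistic is discrete, and exact
between-group dosage-sum ties put a probability atom of roughly 7–9% at
χ² = 0, i.e. at p = 1. Null p-values are therefore *tail-calibrated*
(P(p ≤ α) ≈ α for α up to at least 0.2) but not globally uniform: the
Kolmogorov–Smirnov distance from U(0,1) is ≈0.08, located entirely at the
p = 1 atom, at any background allele frequency and for haplotype as well as
individual units. Decisions based on small p are unaffected.

## Composite LD

Burrows' composite disequilibrium needs neither phase nor Hardy–Weinberg
equilibrium: Δ = cov(X, Y)/2 on allele counts X, Y ∈ {0,1,2} with the 1/n
covariance, identical to the count form n_AB/n − 2p_Ap_B. The squared
composite correlation divides by HW-departure-corrected per-site variances
(p_Aq_A + D_A)(p_Bq_B + D_B); this is the only r² form offered because the
naive p·q denominator is not a bounded correlation (on a fixture of five
coupled homozygotes it yields the impossible r = 2). Algebraically the
corrected form equals the squared Pearson correlation of the dosage
vectors, which serves as the module's master oracle. On phased synthetic
data under random mating the composite r² tracks the classical haplotype r²
(mean absolute difference < 0.05 at n = 50 in the test suite).

Pairs with fewer complete individuals than the threshold (default 20) are
reported as NA with a counted reason rather than silently dropped. Pairs
spanning an unplaced locus get NA distance: they appear in the matrix but
not in decay analysis. Decay is mean r² per distance bin, with empty bins
reported. Pooling populations before computing dosage correlations inflates
LD at between-population-divergent sites; in a hybrid-zone scan that
inflation is the signal of interest, so pooling is an explicit flag, not a
default behaviour quietly applied.

## Linked-vs-unlinked contrast

Per-locus F_ST values are split by region label into colour-pattern-linked
and unlinked classes, summarized as mean ± sd (n−1 denominator), and
compared with a two-sided Mann–Whitney U (one-sided available). For
n₁+n₂ ≤ 14 the p-value is exact by full enumeration of all C(n₁+n₂, n₁)
labelings of the pooled midranks, which handles ties without approximation;
beyond that, the normal approximation with tie correction and a 0.5
continuity correction. The switch point is a package choice: enumeration at
14 costs at most 3432 evaluations, and exact-vs-normal agreement is within
0.02 at n₁ = n₂ = 7 (tested). Note that with very few loci per class the
exact test has hard floors — 2/165 ≈ 0.012 is the smallest two-sided p for
8-vs-3 loci, and a 1-vs-1 comparison can only return p = 1.

## qPCR expression and model averaging

Relative expression is efficiency^(Ct_ref − Ct_target) with efficiency
fixed at 2.0 (perfect doubling; a config knob, since dilution-series
calibration is often unavailable). Replicate rows are averaged after
enforcing the < 0.05-fold replicate-spread criterion. Fold changes between
groups are ratios of geometric means — expression is a ratio scale, and
the analysis models log2 expression.

Covariate importance uses BIC-weighted Bayesian Model Averaging: all 2^K
subsets of the candidate covariates are fit by OLS on log2 expression,
BIC = n·ln(RSS/n) + k·ln(n), weights ∝ exp(−BIC/2), and a covariate's
inclusion probability Pr(β≠0) is the summed weight of the models containing
it, reported in percent; model-averaged coefficients treat excluded terms
as zero. The BIC weighting is the unit-information-prior approximation to
posterior model probabilities — a deliberate, documented choice of prior
structure; with other priors the inclusion numbers would shift, so they
should be read as evidence summaries rather than calibrated posterior
probabilities. Repeated wings from the same individual can be handled only
by adding `individual` as a fixed covariate; no random-effects machinery is
included. Rank-deficient subsets are skipped with a warning and the
remaining weights renormalized.

## Synthetic data: what it emulates, what it does not

`default_config` encodes the study conditions the pipeline is meant for:
two races of 30 diploids each plus two admixed individuals (one haplotype
from each population's process, phenotype 0.5, housed in the
dominant-pattern race's sample); eight colour-pattern-linked loci of 600 bp
at 2 kb spacing (selected sites spanning ≈14.6 kb) each carrying two
selected sites — near-fixed between-population differentials at the three
"peak" loci, moderate (0.5–0.7) at the rest, mirroring a region where a few
genes are close to fixation and surrounding loci are elevated — and three
unlinked neutral controls. Neutral sites draw a shared allele frequency per
site from U(0.1, 0.9): common, population-shared variation typical of
markers segregating in both races. The missingness rate defaults to 0 and
is a knob.

Haplotype-block LD among selected sites uses comonotone coupling: selected
sites whose global positions chain within `block_length` (default 14 kb)
share one uniform variate per haplotype, so each site keeps its exact
marginal frequency while within-block LD is maximal. This is a two-block-
haplotype model, not a coalescent with recombination — simple, analytically
checkable, and sufficient to produce the qualitative signature the LD
analysis is designed to detect (high pooled r² among selected sites over
long distances, low background). It does **not** emulate: genealogical
correlation among neutral sites (they are independent given frequencies),
hitchhiking of neutral sites near selected ones, mutation-model realism,
indels, or sequencing error. Passing tests on this generator demonstrate
the statistics and their wiring, not robustness to those real-data
features.

The neutral coalescent sampler (Kingman genealogy, exponential coalescence
at rate C(k,2), Poisson(θ/2 × branch length) mutations under infinite
sites, no recombination) provides the null for Tajima's D and segregating-
site calibrations; `msprime` is used in the test suite as an independent
cross-check, never as the implementation. All generators run off a single
`numpy` Generator in fixed iteration order, so one seed reproduces
byte-identical files across platforms.

The closed-form single-site F_ST oracle plugs population frequencies into
1 − (p_aq_a + p_bq_b)/(p_a(1−p_b) + p_b(1−p_a)); sample H_w and H_b are
unbiased for these components, so the expression is sample-size-free, but
the estimator itself is a ratio with O(1/n) Jensen bias (≈0.02 at n = 10
haplotypes for frequencies 0.9/0.1), which the simulation-vs-oracle test
tolerance (0.03) accommodates.

## Problem sizes and numerical choices

The test suite and acceptance script use scaled problem sizes chosen as
sensible defaults for a desk-scale reproduction: 2000 coalescent replicates
(n=10, θ=5) for null calibration, 2000 neutral trend tests pooled from
seeded datasets, 50 seeds for the F_ST-contrast detection rate, 15
replicates per point of the power-vs-differential curve, and 24-sample qPCR
designs (3 individuals × 2 wings × 2 stages × 2 races). Floats are written
at 6 significant digits; ties in Mann–Whitney enumeration are compared with
a 1e-9 slack; RSS is floored at 1e-300 before taking logs; beta-test
support violations beyond 1e-9 are clamped with a warning.

## Known limitations

* No VCF/BAM ingestion, no alignment construction, no genotype likelihoods
  or imputation: inputs are pre-aligned, pre-called haplotype sequences.
* Gap columns are dropped globally per locus, so a single gapped haplotype
  removes a column for everyone.
* The trend test treats individuals as exchangeable; no relatedness or
  population-structure correction beyond the design itself.
* The Mann–Whitney exact/normal switch at n₁+n₂ = 14 is a convention;
  other software switches elsewhere.
* BMA assumes homoskedastic Gaussian errors on log2 expression and fixed
  effects only.
* Haplotype-based statistics (EHH, haplotype r²) and recombination-rate
  estimation are out of scope; LD is genotype-composite throughout.
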