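# Methods

This note documents the statistical procedures `snpcca` implements,
the defaults it ships with, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Per-SNP canonical correlation (individual-level data)

For each SNP, X is the single dosage column (G = 1) and Y the
standardised phenotype block, by default the two kidney-function
traits (P = 2); the chronic-kidney-disease status indicator can be
appended as a third Y column (`include_status_in_y`), but the default
excludes it and treats status as metadata, since conditioning a
kidney-function analysis on a kidney-disease indicator risks collider
distortion.

The first canonical correlation is obtained from the singular value
decomposition of the whitened cross-covariance
K = Σ_XX^(-1/2) Σ_XY Σ_YY^(-1/2), with all covariances the usual
n − 1-denominator sample estimates. Whitening uses a symmetric
eigendecomposition with an eigenvalue floor of 1e-10; a block whose
minimum eigenvalue falls below the floor raises an error rather than
silently regularising. Canonical correlations are reported
non-negative, and weight signs are fixed by making the first non-zero
entry of each X-side weight vector positive.

Significance uses Wilks' Lambda Λ = Π(1 − rᵢ²) with Rao's F
approximation: with gp = G·P,

    t  = sqrt((G²P² − 4) / (G² + P² − 5))   if gp > 2, else 1
    w  = n − (G + P + 3)/2
    df1 = gp,  df2 = w·t − gp/2 + 1
    F  = ((1 − Λ^(1/t)) / Λ^(1/t)) · (df2 / df1)

For G = 1 this reduces exactly to the overall F statistic of
regressing the dosage on the Y block with df (P, n − P − 1); the test
suite verifies |Δlog₁₀p| < 1e-8 against an independent least-squares
fit on 1,000 simulated SNPs. The genome scan is vectorised (one pass
over Y moments, per-SNP cross-covariances by matrix product) but is
contractually identical to the naive per-SNP computation, which is
also tested.

Multiple testing supports two conventions: `bonferroni_by_count`
(p·m judged at 0.05, m defaulting to the number of SNPs scanned and
overridable for genome-scale totals) and `fixed_genomewide` (raw p
judged at 5e-8).

### Power analysis

The minimum detectable correlation at sample size n uses the Fisher-z
approximation r = tanh((z₁₋α + z_power)/√(n−3)). The one-sided variant
is the default: the detectable-effect question is directional
("at least this large"), and the one-sided form is the convention this
implementation adopts for its reported values (the two-sided variant
is available via `sided="two"`).

## Canonical correlation from summary statistics

Each univariate GWAS effect is standardised to a genotype-phenotype
correlation r_xy = t/√(t² + n − 2), t = β/SE. This t-based form is
used rather than β·√(2·AF·(1−AF)) scaling: the two agree
asymptotically and the t-based form needs no allele frequency.

The phenotypic correlation matrix S_YY is the Pearson correlation of
the standardised-effect columns across the genome. The estimator
assumes those columns are dominated by null SNPs, whose effect
estimates correlate only through the phenotypic correlation; SNPs with
a strong association signal are extreme outliers on the effect scale
and bias the estimate. When per-SNP sample sizes are available, SNPs
with any-trait |z| ≥ 3 are therefore excluded before the correlation
is taken (skipped if that would leave fewer than 10% of SNPs). At
genome scale the trimming is immaterial; on the few-thousand-SNP
tables used in testing it is what keeps the estimate anchored to the
phenotypic correlation. Estimation uses all post-validation SNPs, not
only significant ones. Fewer than 1,000 SNPs triggers a warning;
fewer than 3 is an error.

Input validation drops rows with any zero standard error, non-ACGT
single-base alleles, duplicated variant keys (all copies dropped,
since provenance cannot be arbitrated), or effect-allele frequency
outside [0.01, 0.99] when AF is present.

Per SNP, the joint covariance [[1, sᵀ], [s, S_YY]] is shrunk towards
positive semidefiniteness by repeatedly multiplying off-diagonal
entries by 0.999 until the minimum eigenvalue reaches 1e-12 (at most
10,000 iterations; the diagonal is never touched), then
r₁² = sᵀ S_YY⁻¹ s is solved on the shrunk entries. The per-SNP sample
size for the Wilks test is the minimum across traits (conservative
degrees of freedom; the mean is available via `n_convention="mean"`).

A structural property worth noting: with positively correlated traits,
opposite-sign effect pairs (c, −c) always yield a larger r₁ than
same-sign pairs (c, c) of equal magnitude — the multivariate test is
most sensitive exactly where the kidney-function direction filter
looks.

## Genotype QC and phenotype standardisation

Variant filters apply in a fixed order: non-autosomal removal, MAF
< 0.01, per-variant missingness ≥ 1.5% (inclusive threshold), exact
Hardy-Weinberg p < 1e-5, then removal of any variant still carrying a
missing call (canonical correlation tolerates no missing cells). The
QC report satisfies removed + retained = input per axis, and the
filter pipeline is idempotent on its own output.

The HWE test is the two-sided exact conditional test: given the
observed allele counts, heterozygote counts of matching parity are
enumerated and the p-value is the summed probability of all outcomes
no more likely than the observed one. It is computed in log space via
gammln and verified exhaustively against direct combinatorial
enumeration for every genotype table with total ≤ 50.

Ancestry filtering retains samples whose PC1–PC2 Euclidean distance
from the reference-panel centre is at most `scale` (default 2) times
the maximum reference distance; any scale ≥ 1 retains every reference
point. Kinship and sex-mismatch exclusions are accepted as externally
supplied sample lists, not computed here.

Phenotypes: serum urea (mmol/L) is divided by 2.14 to give BUN
(the molecular-weight ratio of urea to urea nitrogen; configurable,
since reported conventions vary), then log10-transformed and Z-scored
with the n − 1 standard deviation. eGFR uses the rank-based
inverse-normal transformation with the Blom offset 0.375 and average
ranks for ties: Φ⁻¹((r − 0.375)/(n + 0.25)). Constant inputs are
errors for both transforms.

## Discovery follow-up

*Direction filter*: retain SNPs with β_eGFR · β_BUN < 0 with respect
to the same effect allele. A zero effect in either trait fails the
filter — "opposite" is read strictly.

*Harmonisation*: tables join on exact (chrom, pos, ref, effect allele)
keys; with `allow_swap`, sites whose alleles are written in the
opposite orientation join with betas sign-flipped and AF complemented,
except A/T and C/G strand-ambiguous sites, which never join via swap.

*Clumping* follows the FUMA SNP2GENE convention: greedy by ascending
p-value (ties broken by genomic order), significant SNPs with r² < 0.6
to every previously chosen SNP are *independent significant* SNPs;
among those, r² < 0.1 defines *lead* SNPs; loci span each lead's
dependents and merge when closer than 250 kb. LD r² is taken from a
dense matrix or computed as squared dosage correlation from a genotype
panel; pairs on different chromosomes or more than 1 Mb apart are
treated as unlinked (r² = 0), which bounds computation and matches
common practice. Every significant SNP lands in exactly one locus.

*Nearest gene*: minimum distance to a 1-based inclusive gene interval
(BED input is converted from 0-based half-open on read), distance 0
inside a body; ties break by smaller interval then lexicographic
symbol.

## Colocalisation

Wakefield's approximate Bayes factor per SNP,
log ABF = ½log(1 − r) + ½z²r with r = W/(W + varbeta), prior effect
SD 0.15 (the quantitative-trait convention). Hypothesis weights follow
the standard five-hypothesis single-causal-variant decomposition with
per-SNP priors p1 = p2 = 1e-4 and p12 = 1e-6; regions pair on variant
keys within a ±200 kb window (boundary inclusive), accepting
allele-swapped matches except at strand-ambiguous sites; PP4 > 0.8
declares colocalisation. All accumulation is in log space with
log-sum-exp — regions with |z| > 30 overflow linear space — and the
H3 pairwise sum is computed as log(exp(ℓ₁+ℓ₂) − exp(ℓ₁₂)) with an
underflow guard for the single-dominant-SNP limit. For regions
identified by the canonical correlation scan, the per-SNP (beta,
varbeta) fed to colocalisation are the univariate statistics of a
driving trait (eGFR by default, configurable), since the canonical
correlation itself carries no signed effect.

## Overlap enrichment

Expected overlap under independence is n₁n₂/N for two sets and
n₁n₂n₃/N² for three; fold = observed/expected. Pairwise significance
is the exact hypergeometric upper tail P(X ≥ observed). The triple
case has no standard closed-form null, so the upper tail of a Poisson
at the independence mean is used and flagged as
`poisson_approximation` in the output.

## Differential expression and allele frequency

Differential expression uses a per-gene Welch (unequal-variance)
two-sample test on log₂ expression with Benjamini-Hochberg adjustment.
This is a deliberate simplification relative to moderated-statistics
microarray pipelines: the package's claims about this stage are
threshold-logic and simulation-based, not a microarray re-analysis. A
gene passes only when |log2FC| ≥ 1 **and** BH-adjusted p < 0.05.

Allele-frequency follow-up builds the 2×2 allele-count table (the
contingency unit is alleles, 2n) between a cohort subgroup and a
population reference. Two gates are encoded because the analysis
conventions differ between screening and reporting: |Δaf| ≥ 10%
shortlists a SNP for testing, and significance requires |Δaf| > 15%
plus Yates-corrected chi-square p < 0.05. The Yates statistic floors
each cell's contribution at zero when |O − E| < 0.5.

## Synthetic cohorts

The generator produces every input the pipeline consumes, with the
structure the analysis assumes:

- **Genotypes**: per LD block, exchangeable-correlation latent
  Gaussians (z = √ρ·shared + √(1−ρ)·own) thresholded at each SNP's
  Hardy-Weinberg genotype quantiles, so marginals are exactly HWE at
  the drawn MAF. Defaults: 2,000 samples × 2,000 SNPs, MAF uniform on
  (0.05, 0.45), blocks of 10 at latent ρ = 0.4.
- **Phenotypes**: sparse causal architecture — 20 causal SNPs with
  correlation-scale effects 0.15 on standardised dosages, BUN-side
  signs opposite to eGFR by default, residual noise bivariate normal
  with correlation −0.5 (eGFR and BUN are physiologically
  anti-correlated) scaled so each latent has approximately unit total
  variance. Latents map monotonically onto plausible raw scales (eGFR
  into 3.3–139 ml/min/1.73 m² via a normal-CDF map; urea as
  2.14·10^(0.8 + 0.25·z) mmol/L, so the log-Z transform recovers the
  latent exactly) to exercise the standardisation code on realistic
  magnitudes. Cases are the lowest-eGFR half of the cohort by default.
- **Summary statistics**: per-SNP, per-trait simple OLS slope, SE, t
  p-value, n and effect-allele frequency on the standardised
  phenotypes.
- **eQTL region pairs**: 100-SNP regions with z ~ N(0,1) nulls and one
  causal variant of expected |z| = 12, shared or distinct between the
  pair.
- **Expression**: log₂-scale Gaussian matrices (per-gene baselines
  uniform on 4–12, noise SD 0.2) with a planted fraction of genes
  shifted by ±1.2 in cases.

Every generator is a pure function of its spec and seed; per-stage
streams derive from the cohort seed by fixed offsets, so stages are
reproducible independently.

What the generator does **not** emulate: realistic demography or
coalescent LD (blocks are exchangeable, real LD decays), imputation
error, ancestry admixture, genotyping batch effects, case-control
ascertainment beyond thresholding on eGFR, or microarray
normalisation artefacts. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every failure mode of real cohort data.

## Problem sizes used in validation

The shipped test and acceptance runs use desk-scale problem sizes
chosen as the package's own validation conditions: 2,000 × 2,000
cohorts for engine agreement, 10,000 independent SNPs at n = 500 for
null calibration, 1,000 SNPs for the least-squares oracle, 100 seeded
region pairs for colocalisation recovery, and exhaustive enumeration
up to N = 12 (hypergeometric) and totals of 50 (HWE). Genome-scale
SNP totals enter only as Bonferroni denominators, which are exact at
any scale.

## Known limitations

- Multi-SNP (G > 1) scans are supported by the engine but the
  summary-statistic variant is single-SNP only (no reference-panel LD
  blocks for S_XX).
- The colocalisation model assumes at most one causal variant per
  trait per region.
- The triple-overlap p-value is an approximation (see above).
- The per-SNP F test's type-I error relies on large-sample behaviour
  of discrete dosages; calibration is verified at n = 500, not for
  very small cohorts.
- Binary-trait liability conversions for summary statistics are out of
  scope.
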