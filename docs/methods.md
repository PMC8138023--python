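# Methods

This note documents the models, the estimation machinery, the
synthetic-data generator and the numerical choices behind `rohdep`,
including what the validation experiments do and do not show.

## ROH detection

The caller is a scanning-window algorithm in the PLINK `--homozyg`
family. For one individual on one chromosome (SNPs in bp order):

1. Every complete window of `window_snp` consecutive SNPs *qualifies*
   if it contains at most `window_het` heterozygotes and
   `window_missing` missing calls.
2. A SNP is a *hit* if the fraction of qualifying windows among the
   complete windows overlapping it is at least `hit_threshold`
   (default 0.05, the conventional value; edge SNPs are evaluated over
   the windows that exist — no phantom windows, so behaviour at
   chromosome ends is deterministic).
3. Maximal runs of hit SNPs are candidate segments; a candidate is
   split wherever consecutive SNPs are more than `max_gap_kb` apart,
   then trimmed until both terminal SNPs are homozygous non-missing
   calls.
4. A segment is emitted iff it has ≥ `min_snp` SNPs, length ≥ `min_kb`
   (length = end − start + 1 bp, 1-based inclusive), mean density
   length/SNP-count ≤ `density_kb_per_snp`, and ≤ `segment_het`
   heterozygotes. Missing calls inside a segment count toward length
   and density but not heterozygosity. Runs separated by a single
   non-hit SNP are not merged.

Defaults (50 / 50 / 1200 Kb / 300 Kb / 200 Kb-per-SNP / 2 / 2 / 2) are
the standard parameterisation for ~50K-density array data in a
~2.5 Gb ruminant genome. The density parameter is interpreted as
Kb-per-SNP (the `--homozyg-density` convention); the gap parameter is
in Kb.

The caller is verified segment-for-segment against an independent
brute-force enumerator that applies every rule literally, across
several hundred randomized fixtures and several parameterisations.

## Inbreeding coefficients and length classes

F_ROH is the summed ROH length over the genome length; the default
2452 Mb is the autosomal total of the sheep assembly this pipeline is
calibrated to, while synthetic genomes use their configured total.
Leave-one-chromosome-out values divide the off-chromosome ROH sum by
the off-chromosome genome length.

Length classes use the expected physical length of an IBD tract whose
haplotypes coalesce g generations ago, (100/2g) cM divided by the
genome-wide rate (default 1.28 cM/Mb): g = 2, 4, 8, 16, 32 give
boundaries 19.5, 9.8, 4.9, 2.4 and 1.2 Mb. Bins are half-open on
physical length, `[lower, upper)`, with a boundary-length segment
assigned to the longer-length (more recent MRCA) class; a catch-all
class below the oldest boundary makes the class fractions sum exactly
to F_ROH. The half-open convention is a choice — closed bins would
differ only for segments landing exactly on a boundary.

## ROH landscape

Per-SNP population ROH density is the proportion of individuals with a
segment covering the SNP's position. Windows tile each chromosome from
bp 1 in 500 Kb steps (configurable); per-window density and observed
heterozygosity are means over contained SNPs, and window recombination
rate is the cM span over the Mb span of the first and last SNP inside
the window (SNP-anchored rather than interpolated edges, which is
robust to map gaps; single-SNP windows get 0). Windows without SNPs
are dropped; windows with fewer than 35 SNPs are excluded from
island/desert ranking. The top and bottom `max(1, floor(0.005 N))`
windows by density are islands and deserts, ties broken by genomic
order so the labelling is order-invariant.

The density model is `density ~ z(recomb) + z(het) + (1|chromosome)`
by REML (statsmodels MixedLM). Marginal R² is var(Xβ) over
var(Xβ) + σ²_chromosome + σ²_residual; the semi-partial R² of a
predictor is the marginal R² drop when it is removed (same random
structure). Confidence intervals come from a parametric bootstrap
(default 100 refits of data simulated from the fitted parameters,
seeded); percentile intervals can sit slightly below the point
estimate because bootstrap refits re-estimate variances.

## Survival models and estimation

The annual-survival model is a binomial-logit GLMM: fixed effects are
an intercept, F_ROH (mean-centred over analysis rows and scaled ×10 so
slopes read per 10 % inbreeding), life-stage offsets (lamb reference;
early = ages 1–2, mid = 3–4, late = 5+), sex, twin, and
F_ROH × stage interactions; random intercepts for capture year, birth
year and individual; optionally a pedigree additive effect with
covariance A σ²_A entered through the Cholesky factor of A (tabular
method). If σ_A estimates at the boundary the model refits without the
term and says so in the results. The lethal-equivalents model is the
same data refit with a Poisson distribution and log link and simplified
fixed effects (F_ROH, age, age² entered raw, twin, sex);
2B = −(slope per 10 %-unit)/0.10 × 2, with its interval obtained by
transforming the slope's Wald interval endpoints.

Estimation is Laplace-approximate maximum likelihood written for this
package: penalized IRLS finds the joint mode of the fixed and
spherical random effects for fixed variance scales, and Nelder–Mead
minimizes the profiled criterion

    deviance + u' D⁻¹ u + log det(Z'WZ + D⁻¹) + log det D

over the log standard deviations. Because every grouping factor is
one-hot, the largest factor's cross-product block is diagonal and is
eliminated analytically each step, leaving a small dense system — fits
with thousands of individual intercepts take seconds. Fixed effects
are profiled at the joint mode (the `nAGQ = 0` flavour of Laplace)
rather than carried in the outer optimization; against `lme4::glmer`
on matched data (the test suite runs this cross-check through Rscript)
slopes and variance scales agree to a small fraction of a standard
error at study-scale sizes, while the Poisson intercept carries a
known offset of roughly half the summed random-effect variance — the
quantities this package reports (slopes, odds ratios, variance
components, 2B) are unaffected. Wald standard errors come from the
fixed-effect block of the inverse penalized Hessian; odds ratios are
exact exponentials of the log-odds estimates. Boundary variance
estimates (sd < 10⁻³) are reported as such, never jittered;
coefficients above 15 in absolute value raise a separation flag.

## Association scan

Per SNP, the same binomial machinery fits survival on: allele-A and
allele-B ROH status (homozygous for that allele *and* covered by one
of the individual's ROH; heterozygous or missing genotypes are 0/0 and
the two flags are never both 1), additive dosage, F_ROH computed from
all chromosomes except the focal one, age, age², sex, twin and the top
7 principal components of the variance-standardised genomic
relationship matrix (genotypes centred by 2p and scaled by
√(2p(1−p)); eigenvector signs fixed by making the largest-magnitude
loading positive). PCs stand in for a per-SNP pedigree term, which
would be computationally impractical. ROH-status terms with fewer than
5 carrier individuals are dropped and flagged (separation guard);
per-SNP non-convergence is flagged and the scan continues.

By default the three variance components are estimated once under a
no-SNP-terms null model and fixed for every per-SNP fit (the standard
mixed-model-GWAS device); `vc="per-snp"` re-estimates them per SNP and
agrees closely at a large multiple of the cost.

Multiple testing: SNPs are processed in consecutive blocks of 1000 per
chromosome; each block's composite-LD correlation matrix (Pearson
correlation of unphased genotype codes, missing pairwise-deleted,
constant SNPs contributing zero correlation) is eigendecomposed and
contributes the smallest k whose top eigenvalues reach 99.5 % of the
total; n_eff sums over blocks, and the genome-wide threshold is
α/(2 n_eff) for the two tests per model. Block size matters only when
individuals are fewer than the block size (rank deficiency caps a
block's contribution) — a documented diagnostic, not a hidden
constant.

Sign enrichment pools all non-dropped ROH-status estimates: a
two-sided exact binomial test of negative vs positive counts against
0.5, and two logistic models of direction (negative = 1) on the
absolute estimate and on the p-value. The absolute estimate is used
for the magnitude model; the raw estimate is the documented
alternative.

## Synthetic data generator

Pedigrees are discrete-generation: founders, then `n_per_generation`
offspring per generation from matings among the previous generation
(two offspring per pair so full sibs exist); `full_sib_enriched`
converts a configurable fraction of matings to full-sib pairs. Gene
drop assigns each founder two uniquely labelled haplotypes with
alleles drawn site-independently from per-SNP allele frequencies
(uniform on [0.1, 0.5] by default): founders are in linkage
equilibrium, so multi-SNP homozygous runs arise only from genuine IBD
and every true tract is recorded where the two inherited labels
coincide. Meioses place crossovers as a Poisson process on the cM
scale with no interference, which makes an IBD tract with MRCA g
generations back exponential with mean 100/(2g) cM — the same mapping
the length classes use. Maps are uniform (cM proportional to bp)
per chromosome.

Survival is generated from exactly the fixed- and random-effect
structure the fitted model assumes, with per-level year effects shared
across individuals and observations stopping after the first death.
Default effect sizes emulate the target study system: lamb odds ratio
0.40 per 10 % F_ROH, weaker depression at later stages (late-stage
interaction +0.91 nearly cancels the slope), lamb survival ≈ 0.45 and
adult ≈ 0.75, male and twin disadvantages of −0.3 log-odds, and
year/birth-year/individual variances 0.3/0.2/0.2 — magnitudes for
which no published value exists and which are therefore free,
documented parameters. F_ROH for cohort-only simulations is drawn as
0.18 + 0.30 × Beta(1.6, 6.4) (mean ≈ 0.24, sd ≈ 0.04, range
0.18–0.48), matching a persistently inbred population. Planted
deleterious loci add their log-odds penalty whenever the designated
allele is homozygous inside a *true* IBD tract (generative truth kept
independent of caller behaviour; penalising called-ROH carriers is the
configurable alternative).

Under the log link (used to validate the lethal-equivalents route) the
survival probability is min(exp(η), 1) and the year/id variances
default to small values (0.03/0.02/0.02): log-scale effects are
multiplicative on survival and large year effects would saturate the
cap.

The generator reproduces what it is designed to reproduce — IBD-driven
ROH, the stated survival structure, planted effects. It does not
emulate genotyping error, background LD among founders, mutation,
selection during the simulation, overlapping generations or realistic
N_e trajectories; passing tests therefore demonstrate correctness of
the estimators under the model's assumptions, not robustness to array
artefacts or model misspecification.

## Validation experiments and their scales

- **Odds-ratio recovery**: 20 replicates of 6000 individuals
  (~12–13K individual-years each), planted lamb OR 0.40; the median
  fitted OR recovers truth within ±0.05.
- **Lethal equivalents**: 20 replicates of 6000 individuals simulated
  under the log link with the slope implied by 2B = 4.57; median
  recovered 2B within ±0.4.
- **Null calibration**: 200 replicates of 800 individuals with the
  inbreeding effects zeroed give an F_ROH Wald rejection rate near the
  nominal 5 %.
- **Null scan**: populations of ~580 study individuals from a
  sustained small-N_e demography (20 founders, 20 generations × 48,
  mean F_ROH ≈ 0.2) on a 26 × 15 Mb genome, ~500 SNPs scanned per
  population. The 26-chromosome genome matters: the scan's
  leave-one-chromosome-out inbreeding covariate only controls the
  shared carrier-survival luck if the focal chromosome is a small
  genome fraction. At this scale the pooled fraction of negative
  estimates retains a small positive excess (1–3 points above 50 %)
  from small-sample behaviour of covariate-adjusted fits with ~40–50
  carriers per term; the excess shrinks with carrier count and is
  negligible at real-study scale.
- **Planted locus**: 10 replicates on an 8 × 25 Mb genome; one
  recessive locus with −1.5 log-odds planted at the site with the most
  homozygous-in-IBD carriers. Because carriers share multi-megabase
  ROH, detection is scored regionally: the scan's smallest-p term must
  be a negative effect on the planted chromosome within 5 Mb.
- **Gene-drop validity**: 2000 independent full-sib families give mean
  offspring IBD 0.25 ± 0.01 (independent families are essential —
  offspring of one realised sib pair share the sibs' meioses), and
  mean IBD tract lengths for MRCA loops at g = 2 and 3 track
  100/(2g) cM within the ~5 % shortening expected from chromosome-end
  truncation.

## Known limitations

- The Laplace fit profiles fixed effects at the joint mode; intercepts
  under the log link inherit a variance-dependent offset (documented
  above). Wald intervals are first-order and can lose power near
  separation (Hauck–Donner), which is why strongly lethal planted
  effects are detected *less* sharply than moderately strong ones.
- Variance-component estimates at these data sizes are noisy for the
  individual-level intercept (few observations per individual).
- The per-SNP scan at a few hundred individuals shows the small-sample
  sign excess described above; interpret genome-wide sign enrichment
  at small n against a matched null simulation rather than an exact
  50 % reference.
- No X-chromosome handling, no phased data, no VCF input, no
  genotype-error-tolerant (HMM) ROH calling.
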