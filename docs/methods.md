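# Methods

This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic validation does and does not
establish.

## Synthetic cohorts

The generator emulates the statistical structure a rare-variant gene-set
burden study assumes, at desk scale.

**Variant panel.** Genes are laid out on chromosomes 1–22 with 20 kb
bodies and variants drawn uniformly over the body ∪ TSS ± 20 kb cis
window. The minor-allele frequency law is a mixture: with probability 0.3
a singleton-scale point mass at 1/(2N), otherwise Beta(0.08, 5) truncated
to (0, 0.5]. The singleton component reflects that singletons dominate
real rare-deleterious variant sets; the Beta component is heavy-tailed so
that both the 0.1% and 1% rarity thresholds partition the spectrum
non-trivially. The exact spectrum of real deleterious sets is not
reported beyond singleton counts, so these two parameters are free
choices, fixed once. Consequence categories, PolyPhen-style damaging flags
(missense only; NA elsewhere), scaled CADD values straddling the
15-point cutoff, and external AFs present per source with probability 0.7
(log-normally perturbed truth, so external and internal AF disagree
realistically) complete the annotation. ~2% of sites carry a non-PASS
FILTER to exercise the VQSR step.

**Genotypes.** Dosages are Binomial(2, AF) per sample — i.e. exact HWE,
matching the QC assumption — with 0.5% random missingness and 1% of GQ
entries below the 21 threshold. There is no LD, by design (Non-goal):
the downstream methods never exploit LD, and LD-free data makes the PCA
thinning and kernel eigenstructure fully controlled.

**Phenotypes.** The per-sample true burden is the fraction of minor
alleles over the true-deleterious, AF < 1% variants of the causal gene
set, z-scored. AD status is Bernoulli with logit = intercept +
log(1.24)·z + covariate terms (age 0.03/yr, sex 0.20, center ±0.10,
APOE ε4 +1.0, ε2 −0.5) — the 1.24 odds ratio per burden unit is the
discovery-stage condition the pipeline is meant to recover. 3% of samples
are labeled MCI and must be excluded by the analysis. Braak stages come
from a proportional-odds latent logistic variable with six cut points
placed so stages V–VI hold the majority of mass, mirroring the strongly
right-skewed autopsy distributions; effect log(1.16) per burden SD.
Onset ages follow an exponential proportional-hazards law (baseline rate
1/15 beyond age 60, log-HR log(1.14) per burden SD) with administrative
censoring tuned to a 40% censor rate; controls enter as censored at their
observation age. The genome-wide rare-variant count is the sample's true
rare-allele count plus independent Poisson(2000) background, so it is a
genuine confounder of the burden under the alternative yet independent of
status under the null.

**Families.** Nuclear families (2 parents + 2 sibs by default): parental
haplotypes from the AFs, offspring by Mendelian transmission. The
pedigree kinship matrix (self 0.5, parent–offspring 0.25, sibs 0.25) is
emitted for the mixed model; note the IBD estimator reports π̂ (genome
shared ∝ 2×kinship: 0.5 for first-degree pairs).

**Expression.** Bulk: baseline + effect·(z-scored cis rare-carrier
dosage) for designated eGenes (1 SD by default) + case shift (−0.5) for
designated DE genes + unit Gaussian noise. Single cell: negative binomial
(dispersion 0.5) with log-normal per-cell size factors (σ = 1, with a 2%
tail of ~30× libraries so the 2,500 detected-gene ceiling actually
binds), six cell types at cortical-like proportions, multiplicative
per-cell-type case shifts on the DE genes (Ex up, Oli down — opposite
signs are representable by construction), and per-cell mitochondrial
fractions from Beta(2, 48) (mean ≈ 4%) spanning the 5% threshold.

**What passing tests do not show.** The generator has no LD, no
population stratification by default (PC columns are pure noise), no
batch effects, no genotyping error model beyond missingness/GQ, and
Gaussian bulk noise. Calibration and recovery results here therefore
validate the *statistical machinery*, not robustness to those real-data
pathologies.

**Determinism.** All randomness flows from `SimConfig.seed` through named
substreams (CRC-keyed `SeedSequence` spawn keys), so identical configs
produce byte-identical files.

## QC

Filter order: VQSR/biallelic SNV filter and GQ masking first, then sample
missingness (> 5% removed), then variant missingness (> 2% removed,
*after* GQ masking — masked entries count as missing; the report records
the order), then the control-only HWE exact test on rare variants
(removed when p < 10⁻³, boundary retained). The HWE test is the
two-sided Levene–Haldane exact test: the summed probability of
heterozygote counts no more likely than observed, conditional on allele
counts, computed in log-space with a 10⁻¹² tie cushion; it matches an
exact integer-arithmetic enumeration to 10⁻¹⁰ over all configurations
with n ≤ 50.

Relatedness uses method-of-moments IBD on common variants (MAF ≥ 5%):
per-variant expected IBS-class probabilities given IBD state are summed
over the variants mutually observed for a pair, solved for P(IBD=0,1,2),
and summarized as π̂ = P1/2 + P2, clamped to [0, 1] (the component
probabilities are reported unclamped — clamping them first biases
unrelated pairs upward). Pruning keeps one sample per connected component
of the π̂ > 0.185 graph (second-degree), preferring the lowest missing
rate, ties by id. With < 100 common variants the estimates are
unreliable; the chain then skips pruning and records a warning. PCs are
the top-k left singular vectors of the centered, 2p(1−p)-standardized,
mean-imputed common-variant matrix, thinned to one variant per 100 kb
window (there is no LD to prune in synthetic data).

## Variant selection

Rarity: if either external AF is recorded (a recorded 0 counts as
present), the variant is rare iff *every* recorded external AF is
strictly below the threshold — when the two sources disagree across the
threshold this is the conservative conjunction; only when absent from
both does the internal MAF (computed on retained samples, minor-allele
folded) decide. Deleterious: stop-gain, stop-loss, frameshift,
splice-donor, splice-acceptor, or damaging missense; `use_cadd`
additionally requires scaled CADD > 15. Indels are excluded throughout
(SNV-only analysis). Selection output is position-sorted, making it
invariant to input order; weights are 1 or the host gene's pLI.

## Burden models

The raw score averages over the variants observed for each individual, so
scores stay comparable across samples with different missingness; a
sample missing at every selected variant is flagged NaN. Residualization
is OLS on [1, genome-wide rare count, PC1..PC10]; the PCs deliberately
appear both here and in M0–M2 (the covariate lists are quoted as such,
redundancy notwithstanding). The pipeline z-scores the residual burden so
effects read "per SD of residual burden".

- Logistic: ML fit; Wald p. On (quasi-)separation the Wald p is replaced
  by a likelihood-ratio p and the result flagged.
- Family GLMM: penalized quasi-likelihood with a single variance
  component, V = W⁻¹ + τ·2K on the working scale; τ maximizes the
  working-model REML on [0, 5] (bounded scalar search). Deterministic,
  fast at pedigree scale, and exact at τ = 0 (reduces to logistic IRLS —
  tested to 10⁻⁴). PQL's known downward bias in variance components is
  immaterial here because the family structure is shallow.
- Ordinal: proportional-odds logit fitted by Newton–Raphson with analytic
  gradient and Hessian (cut-point starts from the marginal cumulative
  logits, step halving, observed-information Wald covariance). The fit is
  cross-checked against an independent generic-likelihood optimizer to
  10⁻⁶ and, with two categories, reproduces logistic regression to 10⁻⁵.
  The analytic-derivative Newton route is two orders of magnitude faster
  than generic numerical differentiation, which is what makes the
  1,000-replicate calibration runs practical.
- Cox: partial likelihood with Efron ties (Newton precision 10⁻⁹;
  verified against a brute-force Efron grid-search oracle to 10⁻⁴). Age
  is never a covariate in the hazard models; controls are censored at
  their observation age — the alternative (excluding controls) is a
  documented open choice.

Two-sided p-values everywhere; one-sided conversion happens only inside
the Fisher combiner.

## Kernel tests

Q_ρ = S'R_ρS with S the weighted-genotype score against the null-model
residuals and R_ρ = (1−ρ)I + ρ11'. The null covariance of S is
Φ = φ·Z'Z with Z the variance-weighted, covariate-projected weighted
genotypes; the null distribution of Q_ρ is the χ²-mixture with the
eigenvalues of R_ρ^{1/2}ΦR_ρ^{1/2}. P-values use modified four-moment
(Liu-type) matching to a non-central χ² by default; Imhof
characteristic-function inversion (accurate to ~10⁻⁴) is available via
`method="imhof"`. The optimal test minimizes p over the standard grid
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} and corrects by the
one-dimensional integral of the minimum-p statistic's joint null
(burden component × adjusted mixture), with a Bonferroni cap as a
safeguard. Weights default to the Beta(1, 25) density at the internal
MAF. Genes with < 2 carriers are skipped — below that the moment
approximation is meaningless. Family data enter the kernel tests without
kinship adjustment (the shallow structure shifts burden estimates only
slightly; the burden-model comparison with and without kinship is the
check). Meta pooling sums per-cohort (S, Φ) on a shared, zero-padded
variant frame — homogeneous effects only; heterogeneous-effect pooling is
a non-goal.

Small-sample accuracy: at n = 60 with 3 variants the analytic p tracks a
100,000-permutation residual-permutation mid-p to within ~0.01–0.02. That
gap is the difference between the unconditional mixture null and the
discrete null conditional on the residual multiset — it is O(1/n) and
larger than the Monte-Carlo error of the oracle itself, so per-instance
agreement inside the oracle's 99% Monte-Carlo band is not achievable by
any smooth approximation at this sample size; the acceptance suite states
the strict band check and documents its outcome honestly.

## Meta-analysis

Inverse-variance: weights SE⁻², combined SE (Σw)^{−1/2}, normal z.
Directional Fisher: the consensus direction is the discovery (first)
study's; concordant studies contribute p/2, discordant 1 − p/2;
X² = −2Σln(p₁) against χ²(2k). The combined one-sided p is reported
as-is (a flag doubles it), which is the convention that reconciles the
three-study combination arithmetic it reproduces. Best-model selection takes
the minimum p across M0–M2, ties toward the more-adjusted model.

## Expression

eGene tests delegate to the continuous-trait kernel test on the rare
variants inside the cis window (gene body ∪ TSS ± 20 kb, endpoints
inclusive, 1-based — the union reading of "within the gene boundary and
additionally near the TSS"), thresholded by BH-FDR 0.05. Bulk contrasts
use the Welch t-test (pooled-variance behind a flag) and Pearson
correlation with Braak stage. Single-cell order is fixed: filter (200 ≤
detected genes ≤ 2,500; mitochondrial percentage strictly over 5
removed) → per-cell log-normalization ln(1 + 10⁴·count/total) → per-cell
t-tests by cell type or subcluster. Per-cell tests treat cells as
independent and are anti-conservative for sample-level inference; a
pseudobulk option (per-sample means first) is provided, but per-cell is
the default because it is the procedure being reproduced.

## Problem sizes

The test suite uses cohorts of a few hundred to 3,000 samples over
25–150 genes, 1,000-replicate null calibrations at n = 1,000, and
100-replicate recovery runs (n = 2,000 logistic / 800 ordinal / 500 Cox);
`scripts/acceptance.py` runs three cohorts of 1,200 / 1,200 / 240 samples
over 60 genes. These sizes give the calibration checks adequate power
while keeping a full run on one CPU in minutes.

## Known limitations

- PQL (not adaptive quadrature) for the logistic mixed model; adequate
  for shallow pedigrees, biased for deep ones.
- Liu-type moment matching is approximate in extreme tails; use
  `method="imhof"` when tail accuracy matters, and treat n ≲ 100 binary
  kernel p-values as approximate (see above).
- The negative-control contrast reports directions/significance only; it
  does not test calibration of the control sets formally.
- No heterogeneity statistics (I², Q) in the meta module; fixed effects
  only.
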