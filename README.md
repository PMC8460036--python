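# endoburden

Rare-variant gene-set burden analysis of Alzheimer's disease (AD) and its
related phenotypes, built as a reusable, fully tested pipeline with a
synthetic-cohort generator so that every stage can be validated against
known ground truth — no controlled-access data required.

## What it does

Late-onset AD genetics has implicated the endocytic pathway (endosome,
lysosome, trans-Golgi network). This package implements the full analysis
chain used to ask whether *rare deleterious* variants in such a gene set
carry AD risk:

1. **QC** — VQSR/biallelic filtering, GQ < 21 masking, 5% sample and 2%
   variant missingness cutoffs, a control-only Hardy–Weinberg exact test
   (Levene–Haldane, cutoff 10⁻³ on rare variants), PLINK-style
   method-of-moments IBD relatedness with second-degree pruning, and
   ancestry PCs from the frequency-standardized common-variant matrix.
2. **Variant selection** — dual-source rarity (external reference AFs from
   1KG EUR / gnomAD NFE when recorded, cohort-internal MAF otherwise, at
   0.1% or 1%), deleteriousness (stop-gain/-loss, frameshift,
   splice-donor/-acceptor, damaging missense; optional scaled CADD > 15),
   GMT gene sets with deduplicated unions, optional pLI weighting.
3. **Burden models** — the per-individual burden is the weighted fraction
   of minor alleles over the selected variants,

   `raw_i = Σ_j w_j d_ij / (2 Σ_{j observed for i} w_j)`,

   residualized on the genome-wide rare-variant count and ten PCs, then
   fitted with nested covariate sets M0 ⊂ M1 ⊂ M2 (center + PCs; + age,
   sex; + APOE ε2/ε4 counts): logistic regression for AD status, a
   kinship-adjusted logistic mixed model (PQL, random effect covariance
   τ·2K) for family cohorts, proportional-odds ordinal regression for
   Braak stage 0–VI, and Cox proportional hazards (Efron ties, age never a
   covariate) for age-at-onset / age-of-death.
4. **Per-gene kernel tests** — SKAT-style variance-component score tests
   `Q_ρ = S'[(1−ρ)I + ρ11']S` with Beta(1,25) MAF weights, Liu
   moment-matched (or Imhof characteristic-function) p-values, the
   "optimal" minimum-p combination over the standard ρ grid, and
   homogeneous score-pooled multi-cohort meta tests.
5. **Meta-analysis** — fixed-effects inverse-variance pooling and a
   direction-aware Fisher combination of best-model p-values; Bonferroni
   (α = 0.05/8 = 0.00625 for four gene sets × two MAF thresholds) and
   Benjamini–Hochberg FDR.
6. **Expression** — rare-variant eGene kernel tests over the gene body ∪
   TSS ± 20 kb window at FDR 0.05, case/control Welch t-tests and Braak
   Pearson correlations on bulk RNA-Seq, and single-cell preprocessing
   (cells with 200–2,500 detected genes and ≤ 5% mitochondrial counts;
   per-cell log-normalization to 10⁴ total) with per-cell-type
   differential expression.

The synthetic-cohort module generates VCF genotypes in HWE with a
heavy-tailed MAF spectrum, annotations with partial external-AF coverage,
logistic case/control status on the true burden, proportional-odds Braak
stages, proportional-hazards onset ages, Mendelian sibship families with
pedigree kinship, and bulk plus negative-binomial single-cell expression —
with every generating quantity stored in ground-truth files.

## Worked example

```sh
endoburden simulate --seed 7 --n-samples 2000 --out cohort/
endoburden burden --cohort cohort/ --geneset endo_system \
    --maf 0.01 --phenotype ad --out assoc.tsv
```

Or end-to-end from Python (the numbers below are from
`scripts/acceptance.py --seed 1`, three cohorts of 1,200 / 1,200 / 240
samples over 60 genes):

```text
burden_or_ad_discovery     1.185   (p = 0.0092, n = 1178)
burden_or_ad_replication   1.269
braak_or_discovery         1.138
aao_hr_discovery           1.100
meta_ad_or_ivw             1.207   (p_ivw = 2.8e-05, p_fisher = 5e-05)
egene_sensitivity          0.909   (11 true eGenes, FDR 0.05)
```

Read: per standard deviation of residual burden in the endocytic gene set
the odds of AD rise ~19% in the discovery cohort (the generator's true
odds ratio is 1.24); the effect replicates, and inverse-variance pooling
across the three cohorts gives a combined OR of 1.21 at p ≈ 3×10⁻⁵ —
well below the study-wide threshold of 0.00625. The hazard ratio of 1.10
means higher-burden individuals convert to AD earlier. The eGene test
recovers 10 of 11 genes whose expression was generated with a 1-SD cis
rare-variant effect.

## Layout

```
src/endoburden/
  simulate.py     synthetic cohorts with ground truth
  cohort_io.py    VCF / TSV / GMT / MatrixMarket round trips
  qc.py           filters, HWE exact test, IBD, PCA
  selection.py    rarity + deleteriousness rules, gene sets
  burden.py       burden score, residualization, logistic/ordinal/Cox
  glmm.py         kinship logistic mixed model (PQL)
  kernel.py       SKAT-type kernel tests, SKAT-O, score-pooled meta
  meta.py         inverse-variance + directional Fisher, Bonferroni, BH
  expression.py   eGene tests, bulk contrasts, single-cell DE
  pipeline.py     staged study orchestration, negative controls
  cli.py          `endoburden` command-line interface
```

See `docs/methods.md` for the statistical details and design choices.
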