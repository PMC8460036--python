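"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analyses assume: rare
biallelic SNVs in Hardy-Weinberg equilibrium with a heavy-tailed minor-allele
frequency spectrum, case/control status driven by a logistic model on the
true gene-set burden plus clinical covariates, ordinal Braak stages from a
proportional-odds latent variable skewed toward high stages, onset/death
ages from a proportional-hazards model, sibship families with known kinship,
and bulk / single-cell expression with cis rare-variant effects and
case-associated shifts.

The minor-allele frequency law is a Beta(0.08, 5) truncated to (0, 0.5]
mixed with a point mass at singleton-scale frequency, so that both the 0.1%
and 1% rarity thresholds partition the spectrum non-trivially.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .config import SimConfig
from .cohort_io import Cohort
from .datatypes import GeneSet, GenotypeMatrix, TruthRecord

CELL_TYPES = ("Ex", "In", "Ast", "Oli", "Opc", "Mic")
_CELL_TYPE_PROBS = (0.35, 0.12, 0.12, 0.25, 0.08, 0.08)
MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")

_DELETERIOUS_CATS = (
    "stop-gain", "stop-loss", "frameshift", "splice-donor",
    "splice-acceptor", "missense-damaging",
)
_DELETERIOUS_PROBS = (0.15, 0.03, 0.12, 0.05, 0.05, 0.60)
_BENIGN_CATS = ("missense-benign", "synonymous")

_GENE_SPACING = 200_000
_GENE_LENGTH = 20_000
_CIS_FLANK = 20_000


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from the config seed."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(key,))
    )


def maf_spectrum_cdf(x: float, cfg: SimConfig) -> float:
    """CDF of the generator's MAF law at ``x`` (mixture closed form)."""
    trunc = beta_dist.cdf(0.5, cfg.maf_beta_a, cfg.maf_beta_b)
    cont = beta_dist.cdf(x, cfg.maf_beta_a, cfg.maf_beta_b) / trunc
    singleton_af = 1.0 / (2 * cfg.n_samples)
    point = 1.0 if x >= singleton_af else 0.0
    return cfg.singleton_weight * point + (1 - cfg.singleton_weight) * cont


def gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic gene coordinates: body, TSS and cis window (1-based)."""
    idx = np.arange(cfg.n_genes)
    chrom = (idx % 22) + 1
    rank_within = idx // 22
    start = 1_000_000 + rank_within * _GENE_SPACING
    end = start + _GENE_LENGTH
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i + 1:04d}" for i in idx],
            "chrom": chrom.astype(str),
            "start": start,
            "end": end,
            "tss": start,
            "window_start": np.maximum(start - _CIS_FLANK, 1),
            "window_end": end + _CIS_FLANK,
        }
    )


def _sample_mafs(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    singleton_af = 1.0 / (2 * cfg.n_samples)
    af = np.full(n, singleton_af)
    cont = rng.random(n) >= cfg.singleton_weight
    k = int(cont.sum())
    draws = rng.beta(cfg.maf_beta_a, cfg.maf_beta_b, size=k)
    # truncate to (0, 0.5] by redrawing the (rare) upper-tail exceedances
    bad = draws > 0.5
    while bad.any():
        draws[bad] = rng.beta(cfg.maf_beta_a, cfg.maf_beta_b, size=int(bad.sum()))
        bad = draws > 0.5
    af[cont] = np.clip(draws, 1e-6, 0.5)
    return af


def simulate_variant_panel(cfg: SimConfig) -> pd.DataFrame:
    """Draw a panel of biallelic SNVs with annotations and true AFs.

    Each variant carries coordinates, a gene assignment, a consequence
    category, a PolyPhen-style damaging flag for missense sites, a scaled
    CADD value, and external reference-population AFs present with
    probability ``frac_external_covered`` per source.
    """
    cfg.validate()
    rng = _rng(cfg, "panel")
    genes = gene_table(cfg)
    n_per_gene = 1 + rng.poisson(cfg.variants_per_gene_mean - 1, size=cfg.n_genes)
    rows = []
    bases = np.array(list("ACGT"))
    for g, k in zip(genes.itertuples(index=False), n_per_gene):
        pos = np.sort(rng.integers(g.window_start, g.window_end + 1, size=k))
        pos += np.concatenate([[0], np.cumsum(np.diff(pos) == 0)])  # de-dup
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((g.gene_id, g.chrom, int(p), bases[ref], bases[alt]))
    panel = pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "ref", "alt"])
    m = len(panel)
    panel["variant_id"] = [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(panel.chrom, panel.pos, panel.ref, panel.alt)
    ]
    panel["af_true"] = _sample_mafs(m, cfg, rng)

    deleterious = rng.random(m) < cfg.frac_deleterious
    consequence = np.empty(m, dtype=object)
    consequence[deleterious] = rng.choice(
        _DELETERIOUS_CATS, size=int(deleterious.sum()), p=_DELETERIOUS_PROBS
    )
    consequence[~deleterious] = rng.choice(
        _BENIGN_CATS, size=int((~deleterious).sum())
    )
    panel["consequence"] = consequence
    poly = np.full(m, np.nan)
    poly[consequence == "missense-damaging"] = 1
    poly[consequence == "missense-benign"] = 0
    panel["polyphen_damaging"] = pd.array(
        [int(v) if not np.isnan(v) else None for v in poly], dtype="Int64"
    )
    cadd = np.where(
        deleterious,
        rng.normal(22.0, 6.0, size=m),
        rng.normal(8.0, 4.0, size=m),
    )
    panel["cadd_scaled"] = np.round(np.clip(cadd, 0.0, 60.0), 3)

    noise = rng.lognormal(0.0, 0.3, size=(m, 2))
    ext = np.clip(panel["af_true"].to_numpy()[:, None] * noise, 1e-6, 0.5)
    for i, col in enumerate(("af_kg_eur", "af_gnomad_nfe")):
        present = rng.random(m) < cfg.frac_external_covered
        panel[col] = np.where(present, ext[:, i], np.nan)

    panel["filter"] = np.where(
        rng.random(m) < cfg.frac_filter_fail, "VQSRTrancheSNP99.90", "PASS"
    )
    panel["n_alt_alleles"] = 1
    panel["true_deleterious"] = deleterious
    order = ["variant_id", "chrom", "pos", "ref", "alt", "gene_id", "consequence",
             "polyphen_damaging", "cadd_scaled", "af_kg_eur", "af_gnomad_nfe",
             "af_true", "filter", "n_alt_alleles", "true_deleterious"]
    return panel[order]


def simulate_genotypes(
    panel: pd.DataFrame, cfg: SimConfig, sample_ids=None
) -> GenotypeMatrix:
    """Draw HWE genotypes (dosage ~ Binomial(2, AF)) with missingness and GQ."""
    if len(panel) == 0:
        raise ValueError("variant panel is empty")
    rng = _rng(cfg, "genotypes")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(cfg.n_samples)]
    n, m = len(sample_ids), len(panel)
    af = panel["af_true"].to_numpy()
    dosage = rng.binomial(2, np.broadcast_to(af, (n, m))).astype(float)
    gq = np.where(
        rng.random((n, m)) < cfg.low_gq_rate,
        rng.integers(0, cfg.gq_threshold, size=(n, m)),
        rng.integers(cfg.gq_threshold, 100, size=(n, m)),
    )
    dosage[rng.random((n, m)) < cfg.missingness_rate] = np.nan
    return GenotypeMatrix(sample_ids, panel["variant_id"], dosage, gq)


def _true_burden(
    geno: GenotypeMatrix, panel: pd.DataFrame, gene_set: GeneSet
) -> np.ndarray:
    """Standardized true burden: fraction of minor alleles over the causal set."""
    causal = (
        panel["true_deleterious"]
        & (panel["af_true"] < 0.01)
        & panel["gene_id"].isin(gene_set.genes)
    ).to_numpy()
    if causal.sum() == 0:
        raise ValueError("no causal variants: gene set disjoint from panel genes?")
    D = geno.dosage[:, causal]
    obs = ~np.isnan(D)
    raw = np.nansum(D, axis=1) / np.maximum(2 * obs.sum(axis=1), 1)
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw), raw


def simulate_phenotypes(
    geno: GenotypeMatrix,
    panel: pd.DataFrame,
    gene_set: GeneSet,
    cfg: SimConfig,
    family_ids=None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate status, covariates, Braak stage and time-to-event outcomes.

    Status follows a logistic model on the standardized true burden plus
    covariates; Braak stage comes from a proportional-odds latent logistic
    variable with the configured cut points; onset age follows an
    exponential proportional-hazards law with administrative censoring.
    """
    if not set(gene_set.genes) & set(panel["gene_id"]):
        raise ValueError("gene set shares no genes with the variant panel")
    rng = _rng(cfg, "phenotypes")
    n = geno.n_samples
    z, raw = _true_burden(geno, panel, gene_set)

    age = np.clip(rng.normal(75.0, 8.0, size=n), 55.0, 95.0)
    sex = (rng.random(n) < 0.45).astype(int)  # 1 = male
    center = rng.integers(0, len(cfg.center_effects), size=n)
    apoe_e4 = rng.binomial(2, 0.20, size=n)
    apoe_e2 = np.minimum(rng.binomial(2, 0.07, size=n), 2 - apoe_e4)

    eta = (
        cfg.prevalence_intercept
        + cfg.burden_logOR * z
        + cfg.age_effect * (age - 75.0)
        + cfg.sex_effect * sex
        + np.asarray(cfg.center_effects)[center]
        + cfg.apoe_e2_effect * apoe_e2
        + cfg.apoe_e4_effect * apoe_e4
    )
    case = rng.random(n) < expit(eta)
    status = np.where(case, "case", "control").astype(object)
    mci = rng.random(n) < cfg.frac_mci
    status[mci] = "MCI"

    latent = cfg.braak_logOR * z + 0.5 * case + rng.logistic(size=n)
    braak = np.searchsorted(np.asarray(cfg.braak_cutpoints), latent).astype(float)
    braak[rng.random(n) < cfg.braak_missing_rate] = np.nan

    # exponential PH onset model; controls are administratively censored
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_logHR * z)
    t_raw = cfg.onset_age_floor + rng.exponential(1.0 / rate)
    censor_age = cfg.onset_age_floor + np.quantile(
        rng.exponential(1.0 / cfg.baseline_hazard, size=5000), 1 - cfg.censor_rate
    )
    event = t_raw <= censor_age
    event_time = np.minimum(t_raw, censor_age) - cfg.onset_age_floor + 1e-3

    # genome-wide rare-allele count: causal-set-correlated part plus an
    # independent background; under the null it is independent of status
    rare = (panel["af_true"] < 0.01).to_numpy()
    n_rare_total = (
        np.nansum(geno.dosage[:, rare], axis=1)
        + rng.poisson(cfg.background_rare_mean, size=n)
    )

    pheno = pd.DataFrame(
        {
            "sample_id": geno.samples,
            "status": status,
            "sex": sex,
            "age": np.round(age, 2),
            "center": np.array(["A", "B", "C", "D"])[center],
            "apoe_e2": apoe_e2,
            "apoe_e4": apoe_e4,
            "braak": braak,
            "family_id": family_ids if family_ids is not None else ["NA"] * n,
            "event_time": np.round(event_time, 4),
            "event_flag": event.astype(int),
        }
    )
    pheno["n_rare_total"] = n_rare_total
    pc_noise = _rng(cfg, "pc-noise").normal(size=(n, 10))
    for k in range(10):
        pheno[f"PC{k + 1}"] = np.round(pc_noise[:, k], 6)

    truth = TruthRecord(
        params=cfg.to_dict(),
        sample_truth=pd.DataFrame(
            {
                "sample_id": geno.samples,
                "true_burden_raw": raw,
                "true_burden_z": z,
                "linear_predictor": eta,
            }
        ),
        variant_truth=panel[
            ["variant_id", "gene_id", "af_true", "true_deleterious"]
        ].copy(),
    )
    return pheno, truth


def simulate_families(
    cfg: SimConfig, panel: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Nuclear families: parental HWE haplotypes, Mendelian offspring.

    Returns genotypes, the pedigree-expected kinship matrix (self 0.5,
    parent-offspring 0.25, full sibs 0.25, unrelated 0) and a sample table
    with family ids and roles.
    """
    if cfg.n_families * (cfg.sibship_size + 2) > cfg.family_capacity:
        raise ValueError("family design exceeds configured capacity")
    rng = _rng(cfg, "families")
    af = panel["af_true"].to_numpy()
    m = len(af)
    ids, fam_ids, roles, rows = [], [], [], []
    for f in range(cfg.n_families):
        fam = f"F{f + 1:03d}"
        father = rng.binomial(1, af, size=(2, m)).sum(axis=0)
        mother = rng.binomial(1, af, size=(2, m)).sum(axis=0)
        members = [("father", father), ("mother", mother)]
        for s in range(cfg.sibship_size):
            child = rng.binomial(1, father / 2.0) + rng.binomial(1, mother / 2.0)
            members.append((f"sib{s + 1}", child))
        for role, dos in members:
            ids.append(f"{fam}_{role}")
            fam_ids.append(fam)
            roles.append(role)
            rows.append(dos)
    dosage = np.array(rows, dtype=float)
    n = len(ids)
    kin = np.zeros((n, n))
    fam_arr = np.asarray(fam_ids)
    role_arr = np.asarray(roles)
    for i in range(n):
        kin[i, i] = 0.5
        for j in range(i + 1, n):
            if fam_arr[i] != fam_arr[j]:
                continue
            pair = {role_arr[i], role_arr[j]}
            if pair == {"father", "mother"}:
                phi = 0.0
            else:
                phi = 0.25  # parent-offspring or full sibs
            kin[i, j] = kin[j, i] = phi
    kinship = pd.DataFrame(kin, index=ids, columns=ids)
    samples = pd.DataFrame({"sample_id": ids, "family_id": fam_ids, "role": roles})
    geno = GenotypeMatrix(ids, panel["variant_id"], dosage)
    return geno, kinship, samples


def _nb_counts(rng, mean, dispersion=0.5):
    """Negative-binomial draw parameterized by mean and dispersion (1/size)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))


def simulate_expression(
    geno: GenotypeMatrix,
    panel: pd.DataFrame,
    pheno: pd.DataFrame,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict, TruthRecord]:
    """Bulk expression with cis rare-variant eGene effects, plus single-cell
    negative-binomial counts with per-cell-type case shifts.

    Bulk: expression = baseline + egene_effect * (standardized cis rare
    carrier burden) + case shift + N(0, 1) noise. Single cell: per-cell
    library-size factors, mitochondrial fractions spanning the 5% QC
    threshold, and detected-gene counts spanning the 200/2,500 thresholds.
    """
    rng = _rng(cfg, "expression")
    genes = panel["gene_id"].unique()[: cfg.n_expr_genes]
    status = pheno.set_index("sample_id")["status"].reindex(geno.samples)
    keep = status.isin(["case", "control"]).to_numpy()
    samples = geno.samples[keep]
    is_case = (status.to_numpy()[keep] == "case").astype(float)

    rare = (panel["af_true"] < 0.01).to_numpy()
    egene = rng.random(len(genes)) < cfg.egene_fraction
    de_gene = rng.random(len(genes)) < cfg.de_gene_fraction
    expr = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        in_gene = (panel["gene_id"] == g).to_numpy() & rare
        carrier = geno.dosage[keep][:, in_gene]
        carrier = np.nansum(carrier, axis=1)
        sd = carrier.std()
        zc = (carrier - carrier.mean()) / sd if sd > 0 else np.zeros_like(carrier)
        mu = 6.0 + rng.normal(0, 1.0)
        expr[gi] = (
            mu
            + (cfg.egene_effect * zc if egene[gi] else 0.0)
            + (cfg.bulk_case_shift * is_case if de_gene[gi] else 0.0)
            + rng.normal(0, 1.0, size=len(samples))
        )
    bulk = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)

    sc = _simulate_single_cell(pheno, genes, de_gene, cfg, rng)
    truth = TruthRecord(
        params={"egene_effect": cfg.egene_effect,
                "bulk_case_shift": cfg.bulk_case_shift},
        gene_truth=pd.DataFrame(
            {"gene_id": genes, "is_egene": egene, "is_de_gene": de_gene}
        ),
    )
    return bulk, sc, truth


def _simulate_single_cell(pheno, expr_genes, de_gene, cfg, rng):
    cases = pheno.loc[pheno.status == "case", "sample_id"].to_numpy()
    controls = pheno.loc[pheno.status == "control", "sample_id"].to_numpy()
    k = min(cfg.n_sc_samples // 2, len(cases), len(controls))
    sc_samples = np.concatenate([cases[:k], controls[:k]])
    sc_status = np.array(["case"] * k + ["control"] * k)

    filler = [f"SCG{i + 1:04d}" for i in
              range(cfg.n_sc_genes - len(expr_genes) - len(MITO_GENES))]
    gene_ids = list(expr_genes) + list(MITO_GENES) + filler
    n_genes = len(gene_ids)
    mito_idx = np.arange(len(expr_genes), len(expr_genes) + len(MITO_GENES))
    nonmito = np.setdiff1d(np.arange(n_genes), mito_idx)
    base_mean = np.exp(rng.normal(-1.2, 1.5, size=n_genes))
    base_mean[mito_idx] = 0.0

    shift = {t: cfg.case_shift_per_celltype.get(t, 0.0) for t in CELL_TYPES}
    de_idx = np.flatnonzero(de_gene)

    cells, blocks = [], []
    for sid, st in zip(sc_samples, sc_status):
        nc = cfg.n_cells_per_sample
        ctype = rng.choice(CELL_TYPES, size=nc, p=_CELL_TYPE_PROBS)
        sub = rng.integers(0, 3, size=nc)
        size_factor = rng.lognormal(0.0, 1.0, size=nc)
        big = rng.random(nc) < 0.02  # occasional very large libraries so the
        size_factor[big] *= 30.0     # detected-gene count crosses 2,500
        mito_frac = rng.beta(cfg.mito_beta_a, cfg.mito_beta_b, size=nc)
        for ci in range(nc):
            mean = base_mean * size_factor[ci]
            if st == "case":
                s = shift[ctype[ci]]
                if s != 0.0:
                    mean = mean.copy()
                    mean[de_idx] *= np.exp(s)
            counts = _nb_counts(rng, mean[nonmito])
            full = np.zeros(n_genes, dtype=np.int64)
            full[nonmito] = counts
            f = mito_frac[ci]
            mito_total = rng.poisson(f / (1 - f) * counts.sum())
            if mito_total > 0:
                full[mito_idx] = rng.multinomial(
                    mito_total, np.ones(len(mito_idx)) / len(mito_idx)
                )
            blocks.append(full)
            cells.append((f"{sid}_c{ci:03d}", sid, ctype[ci],
                          f"{ctype[ci]}{sub[ci]}", st))
    counts = scipy.sparse.csr_matrix(np.array(blocks))
    cells_df = pd.DataFrame(
        cells, columns=["cell_id", "sample_id", "celltype", "subcluster", "status"]
    )
    genes_df = pd.DataFrame(
        {"gene_id": gene_ids, "mito": [g.startswith("MT-") for g in gene_ids]}
    )
    return {"counts": counts, "cells": cells_df, "genes": genes_df}


def simulate_cohort(cfg: SimConfig, with_expression: bool = True,
                    with_families: bool = False) -> Cohort:
    """End-to-end generation of one cohort bundle with ground truth."""
    cfg.validate()
    panel = simulate_variant_panel(cfg)
    genes = panel["gene_id"].unique()
    # compartment gene sets mirror the endosome / lysosome / trans-Golgi
    # structure: overlapping subsets of the union "endo-system" set
    rng = _rng(cfg, "genesets")
    n = len(genes)
    endosome = tuple(genes[rng.random(n) < 0.6])
    lysosome = tuple(genes[rng.random(n) < 0.45])
    tgn = tuple(genes[rng.random(n) < 0.15])
    gene_sets = [
        GeneSet("endo_system", tuple(genes), provenance="union"),
        GeneSet("endosome", endosome or tuple(genes[:1]), provenance="GO:0005768"),
        GeneSet("lysosome", lysosome or tuple(genes[:1]), provenance="GO:0005764"),
        GeneSet("trans_golgi", tgn or tuple(genes[:1]), provenance="GO:0005802"),
    ]
    if with_families:
        geno, kinship, fam = simulate_families(cfg, panel)
        pheno, truth = simulate_phenotypes(
            geno, panel, gene_sets[0], cfg, family_ids=fam["family_id"].tolist()
        )
    else:
        geno = simulate_genotypes(panel, cfg)
        kinship = None
        pheno, truth = simulate_phenotypes(geno, panel, gene_sets[0], cfg)
    bulk = sc = None
    if with_expression:
        bulk, sc, expr_truth = simulate_expression(geno, panel, pheno, cfg)
        truth.gene_truth = expr_truth.gene_truth
    return Cohort(
        panel=panel,
        geno=geno,
        pheno=pheno,
        gene_sets=gene_sets,
        gene_windows=gene_table(cfg),
        kinship=kinship,
        bulk=bulk,
        sc_counts=sc["counts"] if sc else None,
        sc_cells=sc["cells"] if sc else None,
        sc_genes=sc["genes"] if sc else None,
        truth=truth,
    )
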