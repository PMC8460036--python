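"""Sample- and variant-level genotype quality control.

Filter chain (in order): variant-quality/biallelic filters and GQ masking,
then sample missingness, then variant missingness, then the control-only
Hardy-Weinberg exact test on rare variants. Relatedness is estimated by
PLINK-style method-of-moments IBD on common variants, and ancestry principal
components by SVD of the frequency-standardized common-variant matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix, QCReport

#: relatedness thresholds on pi-hat (standard IBD conventions)
PIHAT_DUPLICATE = 0.90
PIHAT_FIRST_DEGREE = 0.35
PIHAT_SECOND_DEGREE = 0.185


# ---------------------------------------------------------------------------
# genotype-level and variant-level filters

def mask_low_gq(geno: GenotypeMatrix, gq_threshold: int = 21) -> GenotypeMatrix:
    """Set genotypes with GQ strictly below ``gq_threshold`` to missing."""
    if geno.gq is None:
        raise ValueError("genotype matrix carries no GQ data")
    out = geno.copy()
    out.dosage[out.gq < gq_threshold] = np.nan
    return out


def filter_variants_basic(
    variants: pd.DataFrame, geno: GenotypeMatrix, report: QCReport | None = None
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Keep only FILTER=PASS biallelic SNVs."""
    if "filter" not in variants.columns:
        raise ValueError("variant table has no FILTER column")
    multi = variants.get("n_alt_alleles")
    if multi is not None and (multi > 1).any():
        bad = variants.loc[multi > 1, "variant_id"].head(3).tolist()
        raise ValueError(
            f"multi-allelic sites present (e.g. {bad}); split or drop them upstream"
        )
    snv = (
        variants["ref"].str.len().eq(1)
        & variants["alt"].str.len().eq(1)
        & variants["alt"].ne(".")
    )
    keep = (variants["filter"] == "PASS") & snv
    kept = variants.loc[keep].reset_index(drop=True)
    if report is not None:
        report.add_step("vqsr_biallelic_snv", threshold="FILTER=PASS",
                        n_in=len(variants), n_removed=int((~keep).sum()),
                        axis="variant")
    return kept, geno.subset(variants=kept["variant_id"])


def sample_missingness_filter(
    geno: GenotypeMatrix, cutoff: float = 0.05, report: QCReport | None = None
) -> list[str]:
    """Retain samples whose missing fraction is <= cutoff."""
    rates = geno.sample_missing_rate()
    keep = rates <= cutoff
    if report is not None:
        report.add_step("sample_missingness", threshold=cutoff,
                        n_in=geno.n_samples, n_removed=int((~keep).sum()),
                        axis="sample")
    return list(geno.samples[keep])


def variant_missingness_filter(
    geno: GenotypeMatrix, cutoff: float = 0.02, report: QCReport | None = None
) -> list[str]:
    """Retain variants whose missing fraction is <= cutoff."""
    rates = geno.variant_missing_rate()
    keep = rates <= cutoff
    if report is not None:
        report.add_step("variant_missingness", threshold=cutoff,
                        n_in=geno.n_variants, n_removed=int((~keep).sum()),
                        axis="variant")
    return list(geno.variants[keep])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def _log_het_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every admissible heterozygote count given the
    genotype total ``n`` and minor-allele count ``n_minor`` (conditional on
    allele counts, i.e. the Levene-Haldane distribution)."""
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_major = 2 * n - n_minor
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value: the summed probability of heterozygote
    counts no more likely than the observed one, conditional on allele counts.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * counts[0] + counts[1], 2 * counts[2] + counts[1])
    if n_minor == 0:
        return 1.0
    hets, logp = _log_het_probs(n, n_minor)
    p_obs = logp[np.searchsorted(hets, counts[1])]
    p = np.exp(logp[logp <= p_obs + 1e-12]).sum()
    return float(min(p, 1.0))


def genotype_counts(geno: GenotypeMatrix) -> np.ndarray:
    """Per-variant (hom-ref, het, hom-alt) counts over non-missing calls."""
    d = geno.dosage
    return np.stack(
        [(d == 0).sum(axis=0), (d == 1).sum(axis=0), (d == 2).sum(axis=0)], axis=1
    )


def hwe_filter(
    geno: GenotypeMatrix,
    control_samples,
    rare_mask: np.ndarray,
    cutoff: float = 0.001,
    report: QCReport | None = None,
) -> list[str]:
    """Drop rare variants whose control-only HWE exact p falls below cutoff.

    Non-rare variants are untouched by this filter; the boundary p == cutoff
    is retained (strict inequality).
    """
    controls = geno.subset(samples=list(control_samples))
    counts = genotype_counts(controls)
    keep = np.ones(geno.n_variants, dtype=bool)
    for j in np.flatnonzero(np.asarray(rare_mask)):
        if counts[j].sum() == 0:
            continue
        if hwe_exact_test(*counts[j]) < cutoff:
            keep[j] = False
    if report is not None:
        report.add_step("hwe_controls", threshold=cutoff,
                        n_in=geno.n_variants, n_removed=int((~keep).sum()),
                        axis="variant")
    return list(geno.variants[keep])


# ---------------------------------------------------------------------------
# relatedness (method-of-moments IBD) and pruning

def estimate_relatedness(
    geno_common: GenotypeMatrix, report: QCReport | None = None
) -> pd.DataFrame:
    """PLINK-style method-of-moments P(IBD=0/1/2) and pi-hat per sample pair.

    Expects a common-variant submatrix (internal MAF >= 5%). Per-variant
    expected IBS-class probabilities given IBD state are computed from allele
    frequencies and summed over the variants non-missing for each pair.
    """
    d = geno_common.dosage
    n, m = d.shape
    if m < 100 and report is not None:
        report.warn(f"relatedness estimated on only {m} variants (<100)")
    p = np.nanmean(d, axis=0) / 2.0
    p = np.clip(p, 1e-6, 1 - 1e-6)
    q = 1.0 - p
    # expected P(IBS class | IBD state) per variant
    E = np.stack([
        2 * p**2 * q**2,                      # P(IBS0 | IBD0)
        4 * p**3 * q + 4 * p * q**3,          # P(IBS1 | IBD0)
        p**4 + q**4 + 4 * p**2 * q**2,        # P(IBS2 | IBD0)
        2 * p**2 * q + 2 * p * q**2,          # P(IBS1 | IBD1)
        p**3 + q**3 + p**2 * q + p * q**2,    # P(IBS2 | IBD1)
    ])

    obs = (~np.isnan(d)).astype(float)
    A = [((np.nan_to_num(d) == k) & (obs > 0)).astype(float) for k in (0, 1, 2)]
    nm = obs @ obs.T
    ibs2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    ibs1 = nm - ibs0 - ibs2
    # per-pair expectation sums restricted to mutually observed variants
    S = [(obs * Ek) @ obs.T for Ek in E]

    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(S[0] > 0, ibs0 / S[0], 0.0)
        p1 = np.where(S[3] > 0, (ibs1 - p0 * S[1]) / S[3], 0.0)
        p2 = np.where(nm > 0, (ibs2 - p0 * S[2] - p1 * S[4]) / nm, np.nan)
    # the summary pi-hat is clamped to [0, 1]; the method-of-moments IBD
    # probabilities themselves are reported unclamped (they can stray
    # slightly outside [0, 1] by sampling noise, as in PLINK)
    pihat = np.clip(p1 / 2.0 + p2, 0.0, 1.0)
    pihat[nm == 0] = np.nan

    iu, ju = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "sample_i": geno_common.samples[iu],
            "sample_j": geno_common.samples[ju],
            "ibd0": p0[iu, ju],
            "ibd1": p1[iu, ju],
            "ibd2": p2[iu, ju],
            "pi_hat": pihat[iu, ju],
            "n_variants": nm[iu, ju].astype(int),
        }
    )


def prune_related(
    relatedness: pd.DataFrame,
    missing_rate: dict | None = None,
    threshold: float = PIHAT_SECOND_DEGREE,
) -> list[str]:
    """Keep one sample per connected component of the >threshold pi-hat graph.

    Within a cluster the sample with the lowest missing rate is kept;
    ties break by sample-id order.
    """
    samples = sorted(
        set(relatedness["sample_i"]) | set(relatedness["sample_j"])
    )
    parent = {s: s for s in samples}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    hot = relatedness[relatedness["pi_hat"] > threshold]
    for a, b in zip(hot["sample_i"], hot["sample_j"]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    clusters: dict[str, list] = {}
    for s in samples:
        clusters.setdefault(find(s), []).append(s)
    missing_rate = missing_rate or {}
    kept = []
    for members in clusters.values():
        members.sort(key=lambda s: (missing_rate.get(s, 0.0), s))
        kept.append(members[0])
    return sorted(kept)


# ---------------------------------------------------------------------------
# principal components

def thin_variants(panel_pos: pd.DataFrame, window: int = 100_000) -> np.ndarray:
    """Boolean mask keeping one variant per genomic window per chromosome."""
    key = panel_pos["chrom"].astype(str) + ":" + (
        panel_pos["pos"] // window).astype(str)
    return (~key.duplicated()).to_numpy()


def compute_pcs(geno_common: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k PCs of the centered, frequency-standardized genotype matrix.

    Missing genotypes are mean-imputed; returned PC columns are orthonormal
    left singular vectors (samples x k).
    """
    d = geno_common.dosage.copy()
    p = np.nanmean(d, axis=0) / 2.0
    inds = np.where(np.isnan(d))
    d[inds] = (2 * p)[inds[1]]
    sd = np.sqrt(np.clip(2 * p * (1 - p), 1e-12, None))
    x = (d - 2 * p) / sd
    x[:, sd.squeeze() <= 1e-6] = 0.0
    u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if len(s) else 0
    kk = min(k, rank)
    if kk < k:
        import warnings

        warnings.warn(f"requested {k} PCs but rank is {rank}; returning {kk}")
    pcs = u[:, :kk]
    return pd.DataFrame(
        pcs, index=pd.Index(geno_common.samples, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(kk)]
    )


# ---------------------------------------------------------------------------
# full chain

def run_qc(
    variants: pd.DataFrame,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    *,
    gq_threshold: int = 21,
    sample_miss_cutoff: float = 0.05,
    variant_miss_cutoff: float = 0.02,
    hwe_cutoff: float = 0.001,
    rare_threshold: float = 0.01,
    relatedness_prune: bool = True,
) -> tuple[pd.DataFrame, GenotypeMatrix, QCReport]:
    """The full variant/sample QC chain in the documented order.

    Note: the variant missingness filter runs after GQ masking, so masked
    low-quality genotypes count as missing; the report records the order.
    """
    report = QCReport()
    variants, geno = filter_variants_basic(variants, geno, report)
    if geno.gq is not None:
        geno = mask_low_gq(geno, gq_threshold)
        report.add_step("gq_mask", threshold=gq_threshold,
                        n_in=geno.n_samples * geno.n_variants,
                        n_removed=int(np.isnan(geno.dosage).sum()), axis="entry")
    kept_samples = sample_missingness_filter(geno, sample_miss_cutoff, report)
    geno = geno.subset(samples=kept_samples)
    kept_variants = variant_missingness_filter(geno, variant_miss_cutoff, report)
    geno = geno.subset(variants=kept_variants)
    variants = variants[variants["variant_id"].isin(kept_variants)].reset_index(
        drop=True)

    maf = internal_maf(geno)
    rare_mask = maf < rare_threshold
    controls = pheno.loc[pheno["status"] == "control", "sample_id"]
    controls = [s for s in controls if s in set(geno.samples)]
    kept_variants = hwe_filter(geno, controls, rare_mask, hwe_cutoff, report)
    geno = geno.subset(variants=kept_variants)
    variants = variants[variants["variant_id"].isin(kept_variants)].reset_index(
        drop=True)

    if relatedness_prune:
        maf = internal_maf(geno)
        common = geno.subset(variants=list(geno.variants[maf >= 0.05]))
        if common.n_variants < 100:
            report.warn(
                f"only {common.n_variants} common variants; relatedness "
                "pruning skipped (estimates would be unreliable)")
        else:
            rel = estimate_relatedness(common, report)
            miss = dict(zip(geno.samples, geno.sample_missing_rate()))
            kept_samples = prune_related(rel, miss)
            report.add_step("relatedness_prune", threshold=PIHAT_SECOND_DEGREE,
                            n_in=geno.n_samples,
                            n_removed=geno.n_samples - len(kept_samples),
                            axis="sample")
            geno = geno.subset(samples=kept_samples)
    return variants, geno, report


def internal_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency over non-missing genotypes (monomorphic -> 0)."""
    with np.errstate(invalid="ignore"):
        af = np.nanmean(geno.dosage, axis=0) / 2.0
    af = np.nan_to_num(af)
    return np.minimum(af, 1.0 - af)
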