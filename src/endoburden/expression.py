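"""Expression analyses: rare-variant eGene tests on bulk RNA-Seq,
case/control and Braak-stage contrasts, and single-cell preprocessing with
per-cell-type differential expression.

An eGene is a gene whose expression is associated with the aggregated
effect of the rare variants in its gene body or within 20 kb of its
transcription start site (window boundaries inclusive, 1-based). The
aggregation uses the continuous-trait kernel test; genes are thresholded by
Benjamini-Hochberg FDR at 0.05.

Single-cell processing follows filter -> log-normalize -> test: cells with
fewer than 200 or more than 2,500 detected genes, or with a mitochondrial
count percentage over 5, are removed; counts are normalized per cell to a
fixed total and log1p-transformed; case/control contrasts use Welch
t-tests per cell type (pooled-variance optional; per-sample pseudobulk
optional for a conservative alternative to per-cell tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats

from . import kernel
from .datatypes import GenotypeMatrix
from .meta import bh_fdr

CIS_FLANK = 20_000


def gene_cis_window(gene_row) -> tuple[int, int]:
    """Cis window: gene body united with TSS +/- 20 kb (closed interval)."""
    start = int(gene_row["start"])
    end = int(gene_row["end"])
    tss = int(gene_row["tss"])
    return min(start, tss - CIS_FLANK), max(end, tss + CIS_FLANK)


def variants_in_window(panel: pd.DataFrame, gene_row) -> pd.DataFrame:
    lo, hi = gene_cis_window(gene_row)
    mask = (
        (panel["chrom"].astype(str) == str(gene_row["chrom"]))
        & (panel["pos"] >= lo)
        & (panel["pos"] <= hi)
    )
    return panel.loc[mask]


def egene_test(
    expr_row: np.ndarray,
    geno: GenotypeMatrix,
    window_variants: pd.DataFrame,
    covariates: np.ndarray,
    rare_mask: np.ndarray | None = None,
) -> kernel.KernelResult:
    """Continuous-trait kernel test of one gene's expression on the rare
    variants in its cis window."""
    ids = window_variants["variant_id"].tolist()
    if rare_mask is not None:
        ids = [v for v, r in zip(ids, rare_mask) if r]
    if not ids:
        return kernel.KernelResult("", np.nan, np.nan, 0.0, 0, len(expr_row),
                                   skipped="no rare variants in cis window")
    G = geno.subset(variants=ids).dosage
    null = kernel.fit_null(expr_row, covariates, "continuous")
    maf = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(np.nan_to_num(maf), 1 - np.nan_to_num(maf))
    return kernel.kernel_test(null, G, kernel.beta_maf_weights(maf), rho=0.0)


def scan_egenes(
    bulk: pd.DataFrame,
    geno: GenotypeMatrix,
    panel: pd.DataFrame,
    gene_windows: pd.DataFrame,
    covariates: pd.DataFrame,
    rare_mask: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Kernel eGene test for every bulk gene; BH q-values at the given FDR."""
    samples = [s for s in bulk.columns if s in set(geno.samples)]
    geno = geno.subset(samples=samples)
    cov = covariates.loc[samples].to_numpy(dtype=float)
    rare = panel.loc[rare_mask.reindex(panel.index, fill_value=False)]
    windows = gene_windows.set_index("gene_id")
    rows = []
    for gene_id, expr in bulk[samples].iterrows():
        if gene_id not in windows.index:
            continue
        wv = variants_in_window(rare, windows.loc[gene_id])
        res = egene_test(expr.to_numpy(dtype=float), geno, wv, cov)
        rows.append({"gene_id": gene_id, "Q": res.q, "p": res.p,
                     "n_var": res.n_variants, "skipped": res.skipped})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def de_ttest(values: np.ndarray, is_case: np.ndarray,
             welch: bool = True) -> tuple[float, float, int]:
    """Two-sample t-test of expression between cases and controls.

    Returns (t, two-sided p, direction), with direction the sign of
    mean(case) - mean(control). Welch (unequal variance) by default.
    """
    a = np.asarray(values)[np.asarray(is_case, dtype=bool)]
    b = np.asarray(values)[~np.asarray(is_case, dtype=bool)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per group")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    d = float(a.mean() - b.mean())
    return float(t), float(p), (1 if d > 0 else (-1 if d < 0 else 0))


def braak_correlation(values: np.ndarray, braak: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of expression with Braak stage (pairwise complete)."""
    values = np.asarray(values, dtype=float)
    braak = np.asarray(braak, dtype=float)
    ok = ~(np.isnan(values) | np.isnan(braak))
    r, p = stats.pearsonr(values[ok], braak[ok])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# single-cell

def sc_filter_cells(
    counts: scipy.sparse.spmatrix,
    mito_mask: np.ndarray,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito_pct: float = 5.0,
) -> np.ndarray:
    """Keep cells with min_genes <= detected genes <= max_genes and a
    mitochondrial count percentage <= max_mito_pct (strictly-over removed)."""
    counts = scipy.sparse.csr_matrix(counts)
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, np.asarray(mito_mask, dtype=bool)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return (detected >= min_genes) & (detected <= max_genes) & (
        mito_pct <= max_mito_pct)


def sc_lognormalize(
    counts: scipy.sparse.spmatrix, scale: float = 1e4
) -> scipy.sparse.csr_matrix:
    """Per-cell total-count normalization to ``scale`` followed by log1p."""
    counts = scipy.sparse.csr_matrix(counts, dtype=float)
    total = np.asarray(counts.sum(axis=1)).ravel()
    total[total == 0] = 1.0
    norm = scipy.sparse.diags(scale / total) @ counts
    norm.data = np.log1p(norm.data)
    return norm


def celltype_de(
    normalized: scipy.sparse.spmatrix,
    cells: pd.DataFrame,
    gene_ids,
    target_genes,
    level: str = "major",
    welch: bool = True,
    pseudobulk: bool = False,
) -> pd.DataFrame:
    """Case/control t-test per cell type (or subcluster) for target genes.

    Default is a per-cell test on log-normalized values; ``pseudobulk=True``
    averages per sample first.
    """
    label_col = {"major": "celltype", "subcluster": "subcluster"}[level]
    normalized = scipy.sparse.csr_matrix(normalized)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    for ctype, grp in cells.groupby(label_col, sort=True):
        status = grp["status"].to_numpy()
        if (status == "case").sum() < 2 or (status == "control").sum() < 2:
            rows.append({"celltype": ctype, "gene_id": None, "t": np.nan,
                         "p": np.nan, "direction": 0,
                         "skipped": "fewer than 2 cells per group"})
            continue
        sub = normalized[grp.index.to_numpy()]
        for g in target_genes:
            if g not in gidx:
                continue
            vals = np.asarray(sub[:, gidx[g]].todense()).ravel()
            is_case = status == "case"
            if pseudobulk:
                df = pd.DataFrame({"v": vals, "s": grp["sample_id"].to_numpy(),
                                   "c": is_case})
                agg = df.groupby("s").agg(v=("v", "mean"), c=("c", "first"))
                vals, is_case = agg["v"].to_numpy(), agg["c"].to_numpy()
            try:
                t, p, d = de_ttest(vals, is_case, welch=welch)
                rows.append({"celltype": ctype, "gene_id": g, "t": t, "p": p,
                             "direction": d, "skipped": ""})
            except ValueError as exc:
                rows.append({"celltype": ctype, "gene_id": g, "t": np.nan,
                             "p": np.nan, "direction": 0, "skipped": str(exc)})
    return pd.DataFrame(rows)
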