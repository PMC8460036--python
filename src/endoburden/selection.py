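"""Rare deleterious variant selection and gene-set construction.

Rarity uses a dual-source rule: when a variant is recorded in either of the
two external European reference panels (1KG EUR, gnomAD NFE), it is rare iff
every recorded external AF is strictly below the threshold; only when absent
from both does the cohort-internal MAF decide. Deleteriousness covers
protein-truncating / splice-disrupting consequences plus damaging missense
calls, optionally tightened by scaled CADD > 15.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import DELETERIOUS_CONSEQUENCES, GeneSet, GenotypeMatrix


class SelectionConfig:
    """Threshold and annotation options for rare deleterious selection."""

    def __init__(self, maf_threshold: float = 0.01, use_cadd: bool = False,
                 cadd_cutoff: float = 15.0, weight_scheme: str = "uniform",
                 pli: pd.DataFrame | None = None):
        if maf_threshold <= 0:
            raise ValueError("maf_threshold must be positive")
        if weight_scheme not in {"uniform", "pli"}:
            raise ValueError(f"unknown weight scheme {weight_scheme!r}")
        if weight_scheme == "pli" and pli is None:
            raise ValueError("pli weighting requires a pLI table")
        self.maf_threshold = maf_threshold
        self.use_cadd = use_cadd
        self.cadd_cutoff = cadd_cutoff
        self.weight_scheme = weight_scheme
        self.pli = pli


def compute_internal_af(geno: GenotypeMatrix, retained_samples=None) -> pd.Series:
    """Minor-allele frequency on the retained samples; all-missing variants
    are returned as NaN (flagged)."""
    if retained_samples is not None:
        geno = geno.subset(samples=list(retained_samples))
    obs = (~np.isnan(geno.dosage)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nansum(geno.dosage, axis=0) / (2 * obs)
    maf = np.minimum(af, 1 - af)
    maf[obs == 0] = np.nan
    return pd.Series(maf, index=geno.variants, name="af_internal")


def is_rare(variants: pd.DataFrame, cfg: SelectionConfig) -> np.ndarray:
    """Vectorized dual-source rarity rule.

    A recorded external AF of exactly 0 counts as present. When both
    external AFs are present and disagree across the threshold the variant
    is classified not-rare (conservative conjunction). Comparisons are
    strict ("below" the threshold).
    """
    t = cfg.maf_threshold
    kg = variants["af_kg_eur"].to_numpy(dtype=float)
    gnomad = variants["af_gnomad_nfe"].to_numpy(dtype=float)
    internal = variants["af_internal"].to_numpy(dtype=float)
    has_kg, has_gnomad = ~np.isnan(kg), ~np.isnan(gnomad)
    any_ext = has_kg | has_gnomad
    ext_ok = np.where(has_kg, kg < t, True) & np.where(has_gnomad, gnomad < t, True)
    internal_ok = internal < t
    return np.where(any_ext, ext_ok, internal_ok)


def is_deleterious(variants: pd.DataFrame, cfg: SelectionConfig) -> np.ndarray:
    """Protein-truncating/splice consequences, or damaging missense;
    with ``use_cadd`` additionally require scaled CADD > cutoff."""
    cons = variants["consequence"]
    truncating = cons.isin(DELETERIOUS_CONSEQUENCES).to_numpy()
    missense = cons.isin(["missense-damaging", "missense-benign"]).to_numpy()
    damaging = (
        variants["polyphen_damaging"].fillna(0).astype(int).to_numpy() == 1
    )
    out = truncating | (missense & damaging)
    if cfg.use_cadd:
        out &= variants["cadd_scaled"].to_numpy(dtype=float) > cfg.cadd_cutoff
    return out


def build_gene_sets(gene_sets: list) -> tuple[list, GeneSet, pd.DataFrame]:
    """Deduplicate per-term sets and form the deduplicated union set.

    Returns (per-term sets, union set, pairwise overlap counts).
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    sets = [gs if isinstance(gs, GeneSet) else GeneSet(*gs) for gs in gene_sets]
    union_genes = tuple(dict.fromkeys(g for gs in sets for g in gs.genes))
    union = GeneSet("union", union_genes, provenance="union of all terms")
    overlaps = pd.DataFrame(
        [
            {
                "set_a": a.name,
                "set_b": b.name,
                "n_overlap": len(set(a.genes) & set(b.genes)),
            }
            for i, a in enumerate(sets)
            for b in sets[i + 1:]
        ]
    )
    return sets, union, overlaps


def select_variants(
    variants: pd.DataFrame, gene_set: GeneSet, cfg: SelectionConfig
) -> pd.DataFrame:
    """Rare + deleterious + gene-set-member selection with per-variant weights.

    Weights are 1 under the uniform scheme or the host gene's pLI under the
    pLI scheme. Output is sorted by (chrom, pos) so selection is invariant
    to input order.
    """
    if "af_internal" not in variants.columns:
        raise ValueError("compute_internal_af must be run first")
    mask = (
        is_rare(variants, cfg)
        & is_deleterious(variants, cfg)
        & variants["gene_id"].isin(gene_set.genes).to_numpy()
    )
    sel = variants.loc[mask, ["variant_id", "gene_id", "chrom", "pos",
                              "af_internal"]].copy()
    ext = variants.loc[mask, ["af_kg_eur", "af_gnomad_nfe"]]
    sel["maf_source"] = np.where(
        ext.notna().any(axis=1), "external", "internal"
    )
    if cfg.weight_scheme == "pli":
        pli = cfg.pli.set_index("gene_id")["pli"]
        unknown = set(pli.index) - set(variants["gene_id"])
        if unknown:
            warnings.warn(
                f"{len(unknown)} pLI gene ids not in the variant table; ignored"
            )
        sel["weight"] = sel["gene_id"].map(pli).fillna(0.0).to_numpy()
    else:
        sel["weight"] = 1.0
    sel = sel.sort_values(["chrom", "pos", "variant_id"]).reset_index(drop=True)
    return sel


def genes_with_selected_variants(selected: pd.DataFrame) -> int:
    return int(selected["gene_id"].nunique())
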