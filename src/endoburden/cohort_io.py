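"""Reading and writing a cohort directory.

A cohort directory holds ``cohort.vcf`` (VCFv4.2 with GT and GQ), the
variant annotation table, phenotypes, gene sets (GMT), an optional kinship
matrix, bulk expression, and single-cell counts (MatrixMarket) with cell and
gene metadata. Ground-truth files from the simulator are written alongside
but never consumed by the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    GeneSet,
    GenotypeMatrix,
    TruthRecord,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
)


class ParseError(ValueError):
    """Raised when a cohort file cannot be parsed; names the offending file."""


@dataclass
class Cohort:
    """All tables and matrices of one (synthetic or user-supplied) cohort."""

    panel: pd.DataFrame
    geno: GenotypeMatrix
    pheno: pd.DataFrame
    gene_sets: list = field(default_factory=list)
    gene_windows: pd.DataFrame | None = None
    kinship: pd.DataFrame | None = None
    bulk: pd.DataFrame | None = None
    sc_counts: scipy.sparse.spmatrix | None = None
    sc_cells: pd.DataFrame | None = None
    sc_genes: pd.DataFrame | None = None
    truth: TruthRecord | None = None


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _vcf_lines(panel: pd.DataFrame, geno: GenotypeMatrix):
    yield "##fileformat=VCFv4.2"
    yield "##source=endoburden-simulator"
    for f in sorted(set(panel["filter"]) - {"PASS"}):
        yield f'##FILTER=<ID={f},Description="Failed variant quality recalibration">'
    for chrom in dict.fromkeys(panel["chrom"]):
        yield f"##contig=<ID={chrom}>"
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    has_gq = geno.gq is not None
    if has_gq:
        yield '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    yield "\t".join(cols + list(geno.samples))
    fmt = "GT:GQ" if has_gq else "GT"
    vidx = geno.variant_index(panel["variant_id"])
    for row, j in zip(panel.itertuples(index=False), vidx):
        fields = [
            str(row.chrom), str(row.pos), row.variant_id, row.ref, row.alt,
            ".", row.filter, ".", fmt,
        ]
        dos = geno.dosage[:, j]
        if has_gq:
            gqs = geno.gq[:, j]
            calls = [
                f"{_GT_STRINGS.get(d, './.')}:{int(g)}" for d, g in zip(dos, gqs)
            ]
        else:
            calls = [_GT_STRINGS.get(d, "./.") for d in dos]
        yield "\t".join(fields + calls)


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write all cohort tables to ``directory``; returns the directory path."""
    if len(cohort.panel) == 0 or cohort.geno.n_samples == 0:
        raise ValueError("refusing to write an empty cohort")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    with open(d / "cohort.vcf", "w") as fh:
        for line in _vcf_lines(cohort.panel, cohort.geno):
            fh.write(line + "\n")

    ann = cohort.panel[VARIANT_COLUMNS]
    ann.to_csv(d / "annotations.tsv", sep="\t", index=False, na_rep="NA",
               float_format="%.10g")

    extra = [c for c in cohort.pheno.columns if c not in SAMPLE_COLUMNS]
    cohort.pheno[SAMPLE_COLUMNS + extra].to_csv(
        d / "phenotypes.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.10g")

    with open(d / "genesets.gmt", "w") as fh:
        for gs in cohort.gene_sets:
            fh.write("\t".join([gs.name, gs.provenance or "na", *gs.genes]) + "\n")

    if cohort.gene_windows is not None:
        cohort.gene_windows.to_csv(d / "gene_windows.tsv", sep="\t", index=False)
    if cohort.kinship is not None:
        cohort.kinship.to_csv(d / "kinship.tsv", sep="\t", float_format="%.10g")
    if cohort.bulk is not None:
        cohort.bulk.to_csv(d / "bulk_expr.tsv", sep="\t", float_format="%.10g")
    if cohort.sc_counts is not None:
        scipy.io.mmwrite(d / "sc_counts.mtx",
                         scipy.sparse.coo_matrix(cohort.sc_counts).astype(np.int64))
        cohort.sc_cells.to_csv(d / "sc_cells.tsv", sep="\t", index=False)
        cohort.sc_genes.to_csv(d / "sc_genes.tsv", sep="\t", index=False)

    if cohort.truth is not None:
        with open(d / "truth.json", "w") as fh:
            json.dump(cohort.truth.params, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for name, df in (
            ("truth_samples.tsv", cohort.truth.sample_truth),
            ("truth_variants.tsv", cohort.truth.variant_truth),
            ("truth_genes.tsv", cohort.truth.gene_truth),
        ):
            if df is not None:
                df.to_csv(d / name, sep="\t", index=False, float_format="%.10g")
    return d


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into a GenotypeMatrix plus a site table with FILTER."""
    import cyvcf2

    path = Path(path)
    try:
        reader = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(reader.samples)
    dosage_cols, gq_cols, records = [], [], []
    has_gq = True
    code_to_dosage = np.array([0.0, 1.0, np.nan, 2.0])
    for v in reader:
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        records.append(
            {
                "variant_id": vid,
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "n_alt_alleles": len(v.ALT),
                "filter": v.FILTER or "PASS",
            }
        )
        dosage_cols.append(code_to_dosage[v.gt_types])
        if has_gq:
            try:
                gq = v.format("GQ")
            except KeyError:
                gq = None
            if gq is None:
                has_gq = False
            else:
                gq_cols.append(gq[:, 0])
    if not records:
        raise ParseError(f"{path}: VCF contains no variant records")
    dosage = np.column_stack(dosage_cols)
    gq = np.column_stack(gq_cols).astype(int) if has_gq and gq_cols else None
    sites = pd.DataFrame.from_records(records)
    geno = GenotypeMatrix(samples, sites["variant_id"], dosage, gq)
    return geno, sites


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: GMT line needs name, label, genes")
            sets.append(GeneSet(parts[0], tuple(parts[2:]), provenance=parts[1]))
    return sets


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"], **kw)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_cohort(directory) -> Cohort:
    """Load a cohort directory back into memory (inverse of write_cohort)."""
    d = Path(directory)
    geno, sites = read_vcf(d / "cohort.vcf")
    ann = _read_tsv(d / "annotations.tsv",
                    dtype={"chrom": str, "polyphen_damaging": "Int64"})
    missing = set(VARIANT_COLUMNS) - set(ann.columns)
    if missing:
        raise ParseError(f"{d / 'annotations.tsv'}: missing columns {sorted(missing)}")
    panel = ann.merge(
        sites[["variant_id", "filter", "n_alt_alleles"]], on="variant_id",
        how="left", validate="one_to_one")
    panel["filter"] = panel["filter"].fillna("PASS")

    pheno = _read_tsv(d / "phenotypes.tsv", dtype={"sample_id": str, "center": str})
    gene_sets = read_gmt(d / "genesets.gmt") if (d / "genesets.gmt").exists() else []
    gene_windows = (
        _read_tsv(d / "gene_windows.tsv") if (d / "gene_windows.tsv").exists() else None
    )
    kinship = (
        _read_tsv(d / "kinship.tsv", index_col=0) if (d / "kinship.tsv").exists() else None
    )
    bulk = (
        _read_tsv(d / "bulk_expr.tsv", index_col=0) if (d / "bulk_expr.tsv").exists() else None
    )
    sc_counts = sc_cells = sc_genes = None
    if (d / "sc_counts.mtx").exists():
        try:
            sc_counts = scipy.sparse.csr_matrix(scipy.io.mmread(d / "sc_counts.mtx"))
        except Exception as exc:
            raise ParseError(f"{d / 'sc_counts.mtx'}: {exc}") from exc
        sc_cells = _read_tsv(d / "sc_cells.tsv", dtype={"sample_id": str})
        sc_genes = _read_tsv(d / "sc_genes.tsv")
    return Cohort(
        panel=panel, geno=geno, pheno=pheno, gene_sets=gene_sets,
        gene_windows=gene_windows, kinship=kinship, bulk=bulk,
        sc_counts=sc_counts, sc_cells=sc_cells, sc_genes=sc_genes,
    )
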