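"""End-to-end study orchestration: QC, selection, burden models per cohort,
meta-analysis across cohorts, per-gene kernel scans, and expression
analyses, driven by a single declarative config.

The study design is staged: one discovery cohort, any number of replication
or family cohorts, and a meta-analysis of the best (smallest-p) model per
cohort. Family cohorts are fitted with the kinship-adjusted logistic mixed
model; case-control cohorts with plain logistic regression.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import expression as expr_mod
from . import kernel as kernel_mod
from . import meta as meta_mod
from . import qc as qc_mod
from . import selection as sel_mod
from .cohort_io import Cohort, read_cohort
from .config import StudyConfig
from .datatypes import GeneSet
from .glmm import glmm_burden_test

logger = logging.getLogger("endoburden")


def _get_pcs(cohort: Cohort, geno) -> pd.DataFrame:
    pc_cols = [c for c in cohort.pheno.columns if c.startswith("PC")][:10]
    if pc_cols:
        return cohort.pheno.set_index("sample_id")[pc_cols]
    maf = qc_mod.internal_maf(geno)
    common = geno.subset(variants=list(geno.variants[maf >= 0.05]))
    return qc_mod.compute_pcs(common, k=10)


def _n_rare_total(cohort: Cohort, geno, maf_threshold: float) -> pd.Series:
    if "n_rare_total" in cohort.pheno.columns:
        return cohort.pheno.set_index("sample_id")["n_rare_total"]
    maf = qc_mod.internal_maf(geno)
    rare = geno.dosage[:, maf < maf_threshold]
    return pd.Series(np.nansum(rare, axis=1), index=geno.samples)


def _available_phenotypes(pheno: pd.DataFrame, requested) -> list:
    out = []
    for p in requested:
        if p == "ad" and pheno["status"].isin(["case", "control"]).sum() > 0:
            out.append(p)
        elif p == "braak" and pheno["braak"].notna().sum() > 0:
            out.append(p)
        elif p in ("aao", "aod") and pheno["event_time"].notna().sum() > 0:
            out.append(p)
    return out


def analyze_cohort(
    cohort: Cohort,
    gene_sets: list,
    maf_thresholds,
    phenotypes,
    *,
    is_family: bool = False,
    use_cadd: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """QC one cohort and fit all burden models for every gene-set x MAF
    threshold x phenotype x nested model combination."""
    variants, geno, report = qc_mod.run_qc(
        cohort.panel, cohort.geno, cohort.pheno,
        relatedness_prune=not is_family,
    )
    variants = variants.copy()
    variants["af_internal"] = sel_mod.compute_internal_af(geno).to_numpy()
    pcs = _get_pcs(cohort, geno).reindex(geno.samples)
    pheno = cohort.pheno[cohort.pheno["sample_id"].isin(geno.samples)]
    results = []
    artefacts = {"qc_report": report, "geno": geno, "variants": variants,
                 "pcs": pcs}
    for gs in gene_sets:
        for t in maf_thresholds:
            cfg = sel_mod.SelectionConfig(maf_threshold=t, use_cadd=use_cadd)
            sel = sel_mod.select_variants(variants, gs, cfg)
            if len(sel) == 0:
                logger.warning("no variants selected for %s at MAF<%s", gs.name, t)
                continue
            raw = burden_mod.burden_score(geno, sel["variant_id"], sel["weight"])
            nrt = _n_rare_total(cohort, geno, t).reindex(raw.index)
            resid = burden_mod.residualize(raw, nrt, pcs)
            resid = resid / resid.std() if resid.std() > 0 else resid
            for phen in _available_phenotypes(pheno, phenotypes):
                if phen == "ad" and is_family and cohort.kinship is not None:
                    fits = [
                        glmm_burden_test(resid, pheno, cohort.kinship, m)
                        for m in burden_mod.MODELS
                    ]
                else:
                    fits = burden_mod.fit_all_models(resid, pheno, phen)
                for r in fits:
                    row = r.to_dict()
                    row.update(gene_set=gs.name, maf_threshold=t)
                    results.append(row)
            artefacts[f"selected:{gs.name}:{t}"] = sel
            artefacts[f"burden:{gs.name}:{t}"] = resid
    return pd.DataFrame(results), artefacts


def meta_analyze(per_cohort: dict, alpha: float, n_tests: int) -> pd.DataFrame:
    """Best-model meta-analysis per gene-set x MAF x phenotype."""
    rows = []
    names = list(per_cohort)
    frames = [df.assign(cohort=n) for n, df in per_cohort.items() if len(df)]
    if not frames:
        return pd.DataFrame()
    allres = pd.concat(frames, ignore_index=True)
    threshold = meta_mod.bonferroni_threshold(alpha, n_tests)
    for (gs, t, phen), grp in allres.groupby(
        ["gene_set", "maf_threshold", "phenotype"]
    ):
        inputs = []
        for name in names:  # discovery first: consensus direction
            sub = grp[grp["cohort"] == name]
            if not len(sub):
                continue
            best = sub.loc[sub["p"].idxmin()]
            inputs.append(meta_mod.MetaInput(
                cohort=name, estimate=float(best["estimate"]),
                se=float(best["se"]), p=float(best["p"]),
                direction=int(best["direction"]) or 1,
            ))
        if len(inputs) < 2:
            continue
        ivw = meta_mod.inverse_variance_meta(inputs)
        fish = meta_mod.directional_fisher(inputs)
        rows.append({
            "gene_set": gs, "maf_threshold": t, "phenotype": phen,
            "k": ivw.k, "estimate": ivw.estimate, "se": ivw.se,
            "p_ivw": ivw.p, "p_fisher": fish.p,
            "significant": min(ivw.p, fish.p) < threshold,
            "threshold": threshold,
        })
    return pd.DataFrame(rows)


def gene_scan_cohort(artefacts: dict, pheno: pd.DataFrame, gs_name: str,
                     maf_threshold: float, alpha: float = 0.05):
    """SKAT-O per-gene scan of AD status for one cohort."""
    key = f"selected:{gs_name}:{maf_threshold}"
    if key not in artefacts:
        return pd.DataFrame(), np.nan
    sel = artefacts[key]
    geno = artefacts["geno"]
    pcs = artefacts["pcs"]
    ph = pheno[pheno["sample_id"].isin(geno.samples)]
    ph = ph[ph["status"].isin(["case", "control"])].set_index("sample_id")
    design = burden_mod.model_design(ph, "M2")
    cov = pd.concat([design, pcs.loc[ph.index]], axis=1)
    cov = cov.loc[:, ~cov.columns.duplicated()]
    y = (ph["status"] == "case").astype(float).to_numpy()
    null = kernel_mod.fit_null(y, cov.to_numpy(dtype=float), "binary")
    sub = geno.subset(samples=list(ph.index), variants=sel["variant_id"].tolist())
    vg = pd.Series(sel["gene_id"].to_numpy(), index=sel["variant_id"])
    return kernel_mod.per_gene_scan(
        null, sub.dosage, vg, sel["af_internal"].to_numpy(), alpha=alpha
    )


def expression_analysis(cohort: Cohort, artefacts: dict,
                        maf_threshold: float = 0.01, fdr: float = 0.05):
    """eGene scan plus bulk and single-cell contrasts for one cohort."""
    out = {}
    geno = artefacts["geno"]
    variants = artefacts["variants"]
    pheno = cohort.pheno.set_index("sample_id")
    ok = pheno.index.intersection(geno.samples)
    pheno = pheno.loc[ok]
    cc = pheno[pheno["status"].isin(["case", "control"])]
    design = burden_mod.model_design(cc, "M2")
    pcs = artefacts["pcs"].loc[cc.index]
    cov = pd.concat([design, pcs], axis=1)
    cov = cov.loc[:, ~cov.columns.duplicated()]
    cfg = sel_mod.SelectionConfig(maf_threshold=maf_threshold)
    rare = pd.Series(sel_mod.is_rare(variants, cfg), index=variants.index)
    if cohort.bulk is not None and cohort.gene_windows is not None:
        bulk = cohort.bulk[[c for c in cohort.bulk.columns if c in set(cc.index)]]
        egenes = expr_mod.scan_egenes(
            bulk, geno, variants, cohort.gene_windows, cov, rare, fdr=fdr
        )
        out["egene_results"] = egenes
        targets = egenes.loc[egenes["significant"].fillna(False), "gene_id"]
        de_rows = []
        is_case = (cc["status"] == "case").reindex(bulk.columns).to_numpy()
        braak = cc["braak"].reindex(bulk.columns).to_numpy(dtype=float)
        for g in targets:
            vals = bulk.loc[g].to_numpy(dtype=float)
            t, p, d = expr_mod.de_ttest(vals, is_case)
            r, rp = expr_mod.braak_correlation(vals, braak)
            de_rows.append({"gene_id": g, "t": t, "p": p, "direction": d,
                            "braak_r": r, "braak_p": rp})
        out["de_results"] = pd.DataFrame(de_rows)
        if cohort.sc_counts is not None and len(targets):
            mito = cohort.sc_genes["mito"].to_numpy()
            keep = expr_mod.sc_filter_cells(cohort.sc_counts, mito)
            counts = cohort.sc_counts[keep]
            cells = cohort.sc_cells.loc[keep].reset_index(drop=True)
            norm = expr_mod.sc_lognormalize(counts)
            out["celltype_de"] = expr_mod.celltype_de(
                norm, cells, cohort.sc_genes["gene_id"].tolist(),
                list(targets), level="major",
            )
    return out


def run_study(cfg: StudyConfig, out_dir) -> dict:
    """Execute the staged design end to end and write a results bundle."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_study_inner(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_study_inner(cfg: StudyConfig, out: Path) -> dict:
    cohorts, per_cohort_results, per_cohort_artefacts = {}, {}, {}
    ordered = sorted(cfg.cohorts, key=lambda c: c.role != "discovery")
    for spec in ordered:
        logger.info("stage %s: loading cohort %s", spec.role, spec.name)
        cohort = read_cohort(spec.path)
        _validate_cohort(cohort, cfg)
        cohorts[spec.name] = (spec, cohort)
    gene_sets = _resolve_gene_sets(cfg, cohorts)

    for name, (spec, cohort) in cohorts.items():
        res, art = analyze_cohort(
            cohort, gene_sets, cfg.maf_thresholds, cfg.phenotypes,
            is_family=spec.role == "family", use_cadd=cfg.use_cadd,
        )
        per_cohort_results[name] = res
        per_cohort_artefacts[name] = art
        res.assign(cohort=name).to_csv(
            out / f"assoc_results_{name}.tsv", sep="\t", index=False)
        art["qc_report"].to_json(out / f"qc_report_{name}.json")

    meta_df = meta_analyze(per_cohort_results, cfg.alpha, cfg.n_tests)
    meta_df.to_csv(out / "meta_results.tsv", sep="\t", index=False)

    bundle = {"assoc": per_cohort_results, "meta": meta_df}
    if cfg.run_gene_scan and gene_sets:
        disc = next(n for n, (s, _) in cohorts.items() if s.role == "discovery")
        scan, thr = gene_scan_cohort(
            per_cohort_artefacts[disc], cohorts[disc][1].pheno,
            gene_sets[0].name, cfg.maf_thresholds[0], cfg.alpha,
        )
        scan.to_csv(out / "single_gene_results.tsv", sep="\t", index=False)
        bundle["gene_scan"] = scan
        bundle["gene_scan_threshold"] = thr

    if cfg.run_expression:
        for name, (spec, cohort) in cohorts.items():
            if cohort.bulk is None:
                continue
            expr = expression_analysis(cohort, per_cohort_artefacts[name],
                                       cfg.maf_thresholds[0])
            for key, df in expr.items():
                df.to_csv(out / f"{key}_{name}.tsv", sep="\t", index=False)
            bundle.setdefault("expression", {})[name] = expr

    provenance = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "n_tests": cfg.n_tests,
        "bonferroni_threshold": meta_mod.bonferroni_threshold(
            cfg.alpha, cfg.n_tests),
        "maf_thresholds": list(cfg.maf_thresholds),
        "gene_sets": [gs.name for gs in gene_sets],
        "cohorts": {n: s.role for n, (s, _) in cohorts.items()},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle["provenance"] = provenance
    return bundle


def _validate_cohort(cohort: Cohort, cfg: StudyConfig) -> None:
    need = {"status"}
    if "braak" in cfg.phenotypes:
        need.add("braak")
    if {"aao", "aod"} & set(cfg.phenotypes):
        need |= {"event_time", "event_flag"}
    missing = need - set(cohort.pheno.columns)
    if missing:
        raise ValueError(
            f"phenotype table lacks columns required by the requested "
            f"analyses: {sorted(missing)}"
        )


def _resolve_gene_sets(cfg: StudyConfig, cohorts) -> list:
    _, first = next(iter(cohorts.values()))
    available = {gs.name: gs for gs in first.gene_sets}
    if not cfg.gene_sets:
        return list(available.values())
    out = []
    for name in cfg.gene_sets:
        if name not in available:
            raise ValueError(f"gene set {name!r} not found in cohort GMT")
        out.append(available[name])
    return out


def negative_control_run(
    cfg: StudyConfig, control_sets: list, out_dir
) -> pd.DataFrame:
    """Run the burden pipeline on unrelated (control) gene-sets and contrast
    their significance and directions against the primary gene-sets."""
    if not control_sets:
        raise ValueError("no control gene-sets supplied")
    control_sets = [
        gs if isinstance(gs, GeneSet) else GeneSet(*gs) for gs in control_sets
    ]
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = {s.name: (s, read_cohort(s.path)) for s in cfg.cohorts}
    primary = _resolve_gene_sets(cfg, cohorts)
    per_cohort = {}
    for name, (spec, cohort) in cohorts.items():
        res, _ = analyze_cohort(
            cohort, primary + control_sets, cfg.maf_thresholds, ("ad",),
            is_family=spec.role == "family",
        )
        per_cohort[name] = res
    meta_df = meta_analyze(per_cohort, cfg.alpha, cfg.n_tests)
    primary_names = {gs.name for gs in primary}
    meta_df["role"] = np.where(
        meta_df["gene_set"].isin(primary_names), "primary", "control")
    meta_df.to_csv(out / "negative_control_meta.tsv", sep="\t", index=False)
    return meta_df


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
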