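"""Gene-set burden scores and nested association models.

The burden score is the weighted fraction of alternative minor alleles an
individual carries across the selected rare deleterious variants, averaged
over the variants observed for that individual. Scores are residualized on
the genome-wide rare-variant count and the top ten ancestry PCs before
model fitting. Three nested covariate sets are used throughout:

* M0 - sequencing center and the ten PCs,
* M1 - M0 plus age and sex,
* M2 - M1 plus the APOE e2 and e4 allele counts,

with age dropped from the proportional-hazards variants of M0-M2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .datatypes import AssocResult, GenotypeMatrix
from .polr import polr_fit

MODELS = ("M0", "M1", "M2")


def burden_score(
    geno: GenotypeMatrix, selected_variants, weights=None
) -> pd.Series:
    """Per-sample weighted fraction of minor alleles over selected variants.

    raw_i = sum_j w_j d_ij / (2 * sum_{j observed for i} w_j). Samples
    missing at every selected variant get NaN.
    """
    ids = list(selected_variants)
    if len(ids) == 0:
        raise ValueError("no selected variants")
    sub = geno.subset(variants=ids)
    w = np.ones(len(ids)) if weights is None else np.asarray(weights, dtype=float)
    obs = ~np.isnan(sub.dosage)
    num = np.nansum(sub.dosage * w, axis=1)
    den = 2.0 * (obs * w).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = num / den
    raw[den == 0] = np.nan
    return pd.Series(raw, index=sub.samples, name="burden_raw")


def residualize(
    raw: pd.Series, n_rare_total: pd.Series, pcs: pd.DataFrame
) -> pd.Series:
    """OLS residuals of the raw score on [1, n_rare_total, PC1..PC10]."""
    idx = raw.dropna().index
    y = raw.loc[idx].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(idx)),
            n_rare_total.loc[idx].to_numpy(dtype=float),
            pcs.loc[idx].to_numpy(dtype=float),
        ]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"residualization design is rank deficient ({rank}/{X.shape[1]}); "
            "collinear columns dropped by least squares"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return pd.Series(resid, index=idx, name="burden_residual")


def model_design(
    pheno: pd.DataFrame, model: str = "M2", *, include_age: bool = True
) -> pd.DataFrame:
    """Covariate design for M0/M1/M2 (center dummies + PCs [+ age/sex [+ APOE]])."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    pcs = [c for c in pheno.columns if c.startswith("PC")][:10]
    cols = {}
    centers = sorted(pheno["center"].astype(str).unique())
    for c in centers[1:]:
        cols[f"center_{c}"] = (pheno["center"].astype(str) == c).astype(float)
    for c in pcs:
        cols[c] = pheno[c].astype(float)
    if model in ("M1", "M2"):
        if include_age:
            cols["age"] = pheno["age"].astype(float)
        cols["sex"] = pheno["sex"].astype(float)
    if model == "M2":
        cols["apoe_e2"] = pheno["apoe_e2"].astype(float)
        cols["apoe_e4"] = pheno["apoe_e4"].astype(float)
    return pd.DataFrame(cols, index=pheno.index)


def _align(residual: pd.Series, pheno: pd.DataFrame, outcome_mask) -> pd.DataFrame:
    df = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    df = df.loc[df.index.intersection(residual.index)]
    df = df[outcome_mask(df)]
    df = df.assign(burden=residual.loc[df.index])
    return df


def logistic_burden_test(
    residual: pd.Series, pheno: pd.DataFrame, model: str = "M2"
) -> AssocResult:
    """Logistic regression of AD status on residual burden (MCI excluded).

    On (quasi-)separation the Wald p is replaced by a likelihood-ratio p
    and the result is flagged.
    """
    df = _align(residual, pheno, lambda d: d["status"].isin(["case", "control"]))
    y = (df["status"] == "case").astype(float).to_numpy()
    if df["burden"].nunique() <= 1:
        raise ValueError("burden score has no variation among analysis samples")
    X = model_design(df, model)
    exog = sm.add_constant(
        pd.concat([df[["burden"]], X], axis=1), has_constant="add"
    )
    flags = ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
    est = float(fit.params["burden"])
    se = float(fit.bse["burden"])
    p = float(fit.pvalues["burden"])
    if not np.isfinite(p) or se > 1e3 or np.abs(est) > 1e2:
        # separation fallback: profile likelihood-ratio p for the burden term
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_fit = sm.GLM(
                y, exog.drop(columns="burden"), family=sm.families.Binomial()
            ).fit()
        from scipy.stats import chi2

        lrt = 2 * (fit.llf - null_fit.llf)
        p = float(chi2.sf(max(lrt, 0.0), 1))
        flags = ("separation_lrt_p",)
    return AssocResult(model=model, phenotype="ad", estimate=est, se=se,
                       p=max(p, np.finfo(float).tiny), n=len(df), flags=flags)


def ordinal_burden_test(
    residual: pd.Series, pheno: pd.DataFrame, model: str = "M2"
) -> AssocResult:
    """Proportional-odds (ordinal logistic) model of Braak stage 0-VI."""
    df = _align(residual, pheno, lambda d: d["braak"].notna())
    stages = df["braak"].astype(int)
    if stages.nunique() < 2:
        raise ValueError("need at least two observed Braak categories")
    X = pd.concat([df[["burden"]], model_design(df, model)], axis=1)
    # constant columns are absorbed by the cut points
    X = X.loc[:, X.std() > 0]
    fit = polr_fit(X.to_numpy(dtype=float), stages.to_numpy())
    j = list(X.columns).index("burden")
    est = float(fit.beta[j])
    se = float(fit.bse[j])
    from scipy.stats import norm

    p = float(2 * norm.sf(abs(est) / se))
    return AssocResult(model=model, phenotype="braak", estimate=est, se=se,
                       p=max(p, np.finfo(float).tiny), n=len(df))


def cox_burden_test(
    residual: pd.Series, pheno: pd.DataFrame, model: str = "M2",
    phenotype: str = "aao",
) -> AssocResult:
    """Cox proportional-hazards fit (Efron ties) of age-to-event on burden.

    Controls enter as censored observations; age is never a covariate here.
    """
    df = _align(residual, pheno, lambda d: d["event_time"].notna())
    if df["event_flag"].sum() == 0:
        raise ValueError("no events in the analysis sample")
    X = model_design(df, model, include_age=False)
    data = pd.concat(
        [df[["event_time", "event_flag", "burden"]], X], axis=1
    )
    data = data.loc[:, (data.std() > 0) | data.columns.isin(
        ["event_time", "event_flag", "burden"])]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col="event_time", event_col="event_flag",
                fit_options={"precision": 1e-9})
    est = float(cph.params_["burden"])
    se = float(cph.standard_errors_["burden"])
    p = float(cph.summary.loc["burden", "p"])
    return AssocResult(model=model, phenotype=phenotype, estimate=est, se=se,
                       p=max(p, np.finfo(float).tiny), n=len(data))


def fit_all_models(
    residual: pd.Series, pheno: pd.DataFrame, phenotype: str
) -> list[AssocResult]:
    """Fit M0, M1 and M2 for one phenotype; returns one result per model."""
    fitters = {
        "ad": lambda m: logistic_burden_test(residual, pheno, m),
        "braak": lambda m: ordinal_burden_test(residual, pheno, m),
        "aao": lambda m: cox_burden_test(residual, pheno, m, "aao"),
        "aod": lambda m: cox_burden_test(residual, pheno, m, "aod"),
    }
    if phenotype not in fitters:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    return [fitters[phenotype](m) for m in MODELS]
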