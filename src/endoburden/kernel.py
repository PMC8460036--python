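"""Variance-component (kernel) score tests for rare-variant sets.

For a gene with genotype matrix G (n x m), weights w and a fitted null GLM
with working residuals r and variance weights v, the test statistic is

    Q_rho = S' R_rho S,   S = (G diag(w))' r,
    R_rho = (1 - rho) I + rho 1 1',

so rho = 0 is the pure variance-component kernel and rho = 1 the weighted
burden test. Under the null Q_rho is a mixture of chi-squares whose weights
are the eigenvalues of R_rho^(1/2) Phi R_rho^(1/2), with Phi the covariance
of S after projecting out the covariate design. P-values come from
four-moment (Liu-type) matching by default, with characteristic-function
(Imhof) inversion available behind a flag. The "optimal" test minimizes the
per-rho p over a fixed grid and corrects by one-dimensional integration
over the null of the minimum-p statistic.

Default variant weights are the Beta(1, 25) density at the cohort-internal
MAF. Multi-cohort pooling sums per-cohort score vectors and covariance
matrices over a shared variant frame (homogeneous-effect pooling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, ncx2

RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

#: genes are tested only with at least this many carriers
MIN_CARRIERS = 2


@dataclass
class NullModel:
    """Null GLM fit: fitted means, dispersion and the covariate design."""

    family: str  # binary | continuous
    y: np.ndarray
    X: np.ndarray  # includes intercept
    mu: np.ndarray
    resid: np.ndarray  # y - mu
    v: np.ndarray  # per-sample variance weight
    phi: float  # dispersion (1 for binary, sigma^2 for continuous)
    sample_ids: np.ndarray | None = None


@dataclass
class KernelResult:
    gene: str
    q: float
    p: float
    rho: float
    n_variants: int
    n_samples: int
    skipped: str = ""


def fit_null(y, covariates, family: str, sample_ids=None) -> NullModel:
    """Fit the null model: GLM of the trait on covariates (with intercept)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(y)), X])
    if family == "binary":
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if not fit.converged:
            raise RuntimeError("null model did not converge: "
                               f"deviance={fit.deviance:.3g}")
        mu = fit.fittedvalues
        v = np.clip(mu * (1 - mu), 1e-10, None)
        phi = 1.0
    elif family == "continuous":
        fit = sm.OLS(y, X).fit()
        mu = fit.fittedvalues
        v = np.ones(len(y))
        dof = max(len(y) - X.shape[1], 1)
        phi = float(np.sum((y - mu) ** 2) / dof)
    else:
        raise ValueError(f"unknown trait family {family!r}")
    return NullModel(family=family, y=y, X=X, mu=np.asarray(mu),
                     resid=y - np.asarray(mu), v=v, phi=phi,
                     sample_ids=None if sample_ids is None
                     else np.asarray(sample_ids, dtype=object))


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1, 25) density weights at the cohort-internal MAF."""
    return beta_dist.pdf(np.clip(maf, 1e-6, 1 - 1e-6), a, b)


def score_components(null: NullModel, G: np.ndarray, weights=None):
    """Score vector S and its null covariance Phi for one gene.

    Phi = phi * Z'Z with Z the variance-weighted, covariate-projected,
    weighted genotype columns.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    G = np.nan_to_num(G)  # missing genotypes contribute nothing to the score
    if weights is None:
        weights = np.ones(G.shape[1])
    Gw = G * np.asarray(weights, dtype=float)
    S = Gw.T @ null.resid
    sv = np.sqrt(null.v)
    Z = sv[:, None] * Gw
    Xs = sv[:, None] * null.X
    Qx, _ = np.linalg.qr(Xs)
    Z = Z - Qx @ (Qx.T @ Z)
    Phi = null.phi * (Z.T @ Z)
    return S, Phi


def _mixture_eigenvalues(Phi: np.ndarray, rho: float) -> np.ndarray:
    m = Phi.shape[0]
    R = (1 - rho) * np.eye(m) + rho * np.ones((m, m))
    vals, vecs = np.linalg.eigh(R)
    Rh = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    lam = np.linalg.eigvalsh(Rh @ Phi @ Rh)
    lam = lam[lam > max(lam.max(), 0) * 1e-10] if lam.size else lam
    return lam


def liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Upper-tail probability of sum lam_k chi2_1 at q by modified
    four-moment matching to a (non-central) chi-square."""
    lam = np.asarray(lam, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    if c2 <= 0:
        return 1.0
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    t = (q - c1) / np.sqrt(2 * c2)
    x = t * np.sqrt(2 * (dof + 2 * delta)) + dof + delta
    return float(np.clip(ncx2.sf(x, dof, delta), 0.0, 1.0))


def _liu_params(lam):
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    return c1, c2, dof, delta


def liu_quantile(p_upper: float, lam: np.ndarray) -> float:
    """Approximate upper-tail quantile of the mixture via Liu matching."""
    c1, c2, dof, delta = _liu_params(np.asarray(lam, dtype=float))
    x = ncx2.isf(p_upper, dof, delta)
    t = (x - dof - delta) / np.sqrt(2 * (dof + 2 * delta))
    return float(t * np.sqrt(2 * c2) + c1)


def imhof_pvalue(q: float, lam: np.ndarray) -> float:
    """Exact mixture tail probability by Imhof characteristic-function
    inversion (numerical integration)."""
    lam = np.asarray(lam, dtype=float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=500)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def kernel_test(
    null: NullModel, G, weights=None, rho: float = 0.0, gene: str = "",
    method: str = "liu",
) -> KernelResult:
    """Kernel score test at a fixed rho (rho=0 SKAT-like, rho=1 burden)."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    poly = np.nanstd(G, axis=0) > 0
    if not poly.any():
        return KernelResult(gene, np.nan, np.nan, rho, m, n,
                            skipped="all variants monomorphic")
    carriers = int((np.nan_to_num(G) > 0).any(axis=1).sum())
    if carriers < MIN_CARRIERS:
        return KernelResult(gene, np.nan, np.nan, rho, m, n,
                            skipped=f"fewer than {MIN_CARRIERS} carriers")
    S, Phi = score_components(null, G, weights)
    q = float((1 - rho) * np.sum(S**2) + rho * np.sum(S) ** 2)
    lam = _mixture_eigenvalues(Phi, rho)
    pfun = imhof_pvalue if method == "imhof" else liu_pvalue
    p = pfun(q, lam)
    return KernelResult(gene, q, max(min(p, 1.0), np.finfo(float).tiny),
                        rho, m, n)


def pooled_kernel_p(S, Phi, rho: float, method: str = "liu") -> tuple[float, float]:
    q = float((1 - rho) * np.sum(S**2) + rho * np.sum(S) ** 2)
    lam = _mixture_eigenvalues(Phi, rho)
    pfun = imhof_pvalue if method == "imhof" else liu_pvalue
    return q, max(min(pfun(q, lam), 1.0), np.finfo(float).tiny)


def _optimal_p_from_components(S, Phi, rho_grid, method="liu"):
    """SKAT-O style minimum-p combination over the rho grid."""
    rho_grid = list(rho_grid)
    pvals, qstats = [], []
    for rho in rho_grid:
        q, p = pooled_kernel_p(S, Phi, rho, method)
        pvals.append(p)
        qstats.append(q)
    p_min = min(pvals)
    i_min = int(np.argmin(pvals))
    if len(rho_grid) == 1:
        return pvals[0], rho_grid[i_min], qstats[i_min], pvals

    # null decomposition: Q_rho ~ (1-rho) * kappa + tau(rho) * eta0
    vals, vecs = np.linalg.eigh(Phi)
    A = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T  # Phi^(1/2)
    m = Phi.shape[0]
    zbar = A @ (np.ones(m) / m)
    z2 = float(zbar @ zbar)
    if z2 <= 1e-300:
        return p_min, rho_grid[i_min], qstats[i_min], pvals
    cof = (zbar @ A) / z2  # m-vector
    A2 = A - np.outer(zbar, cof)
    lam = np.linalg.eigvalsh(A2 @ A2.T)
    lam = lam[lam > max(lam.max(), 0) * 1e-10]
    mu_q = lam.sum()
    var_zeta = 4.0 * float(zbar @ A2 @ A2.T @ zbar)
    var_q = 2 * np.sum(lam**2) + var_zeta
    if var_q <= 0 or lam.size == 0:
        # rank-one Phi: every rho gives the same (burden) statistic
        return p_min, rho_grid[i_min], qstats[i_min], pvals
    if np.sum(lam**2) > 0:
        kurt = 12 * np.sum(lam**4) / np.sum(lam**2) ** 2
        df = max(12.0 / kurt, 0.5) if kurt > 0 else 1e4
    else:
        df = 1e4
    tau = np.array([m**2 * r * z2 + (1 - r) * float(np.sum(cof**2)) * z2
                    for r in rho_grid])

    qmin = np.array([
        liu_quantile(p_min, _mixture_eigenvalues(Phi, r)) for r in rho_grid
    ])

    def integrand(x):
        with np.errstate(divide="ignore", invalid="ignore"):
            dlt = np.where(
                np.array(rho_grid) < 1.0,
                (qmin - tau * x) / (1 - np.array(rho_grid)),
                np.inf,
            )
        qx = dlt.min()
        if qx <= 0:
            return 0.0
        # survival of the adjusted mixture at qx via moment-matched chi2
        t = (qx - mu_q) / np.sqrt(var_q) * np.sqrt(2 * df) + df
        return chi2.cdf(t, df) * chi2.pdf(x, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, 40.0, limit=200)
    p_opt = 1.0 - val
    p_opt = min(p_opt, p_min * len(rho_grid))
    p_opt = max(p_opt, p_min, np.finfo(float).tiny)
    return float(p_opt), rho_grid[i_min], qstats[i_min], pvals


def optimal_kernel_test(
    null: NullModel, G, weights=None, rho_grid=RHO_GRID, gene: str = "",
    method: str = "liu",
) -> KernelResult:
    """Optimal burden/variance-component combination over the rho grid."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    if not (np.nanstd(G, axis=0) > 0).any():
        return KernelResult(gene, np.nan, np.nan, np.nan, m, n,
                            skipped="all variants monomorphic")
    if int((np.nan_to_num(G) > 0).any(axis=1).sum()) < MIN_CARRIERS:
        return KernelResult(gene, np.nan, np.nan, np.nan, m, n,
                            skipped=f"fewer than {MIN_CARRIERS} carriers")
    S, Phi = score_components(null, G, weights)
    p, rho_opt, q, _ = _optimal_p_from_components(S, Phi, rho_grid, method)
    return KernelResult(gene, q, p, rho_opt, m, n)


def meta_kernel_test(
    cohort_components: list, rho: float | None = 0.0, rho_grid=RHO_GRID,
    gene: str = "", method: str = "liu",
) -> KernelResult:
    """Homogeneous-effect pooling of per-cohort (S, Phi) for one gene.

    Cohorts must share a variant coordinate frame (missing variants are
    zero-padded by the caller). Passing ``rho=None`` runs the optimal test
    on the pooled components.
    """
    shapes = {np.asarray(S).shape for S, _ in cohort_components}
    if len(shapes) != 1:
        raise ValueError("cohort score vectors are not on a shared variant frame")
    S = np.sum([np.asarray(S, dtype=float) for S, _ in cohort_components], axis=0)
    Phi = np.sum([np.asarray(P, dtype=float) for _, P in cohort_components], axis=0)
    m = len(S)
    if rho is None:
        p, rho_opt, q, _ = _optimal_p_from_components(S, Phi, rho_grid, method)
        return KernelResult(gene, q, p, rho_opt, m, -1)
    q, p = pooled_kernel_p(S, Phi, rho, method)
    return KernelResult(gene, q, p, rho, m, -1)


def per_gene_scan(
    null: NullModel,
    geno_dosage: np.ndarray,
    variant_gene: pd.Series,
    maf: np.ndarray,
    alpha: float = 0.05,
    optimal: bool = True,
    weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """One kernel test per gene with >=1 polymorphic selected variant.

    Returns the per-gene table and the Bonferroni threshold alpha divided by
    the number of genes actually tested.
    """
    if weights is None:
        weights = beta_maf_weights(np.asarray(maf))
    rows = []
    for gene_id, idx in variant_gene.groupby(variant_gene).groups.items():
        cols = variant_gene.index.get_indexer(idx)
        G = geno_dosage[:, cols]
        w = np.asarray(weights)[cols]
        test = optimal_kernel_test if optimal else kernel_test
        res = test(null, G, w, gene=str(gene_id))
        rows.append(res)
    table = pd.DataFrame(
        [
            {"gene": r.gene, "Q": r.q, "p": r.p, "rho_opt": r.rho,
             "n_var": r.n_variants, "n": r.n_samples, "skipped": r.skipped}
            for r in rows
        ]
    ).sort_values("gene").reset_index(drop=True)
    n_tested = int(table["p"].notna().sum())
    threshold = alpha / n_tested if n_tested else np.nan
    return table, threshold


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m <= 0:
        raise ValueError("number of tests must be positive")
    return alpha / m
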