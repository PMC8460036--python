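"""Proportional-odds (cumulative logit) maximum likelihood.

Model: P(Y <= k | x) = sigma(theta_k - x'beta) with strictly increasing
cut points theta_1 < ... < theta_{K-1}. Fitted by Newton-Raphson with
analytic gradient and Hessian and step-halving; Wald covariance from the
inverse observed information. Positive beta shifts mass toward higher
categories (the polr sign convention).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class PolrResult:
    def __init__(self, beta, theta, cov_beta, loglik, n_iter, converged):
        self.beta = beta          # slope coefficients
        self.theta = theta        # cut points
        self.cov_beta = cov_beta  # covariance of the slopes
        self.loglik = loglik
        self.n_iter = n_iter
        self.converged = converged

    @property
    def bse(self):
        return np.sqrt(np.diag(self.cov_beta))


def _loglik(params, X, y, K):
    theta = params[: K - 1]
    beta = params[K - 1:]
    eta = X @ beta
    hi = np.where(y < K - 1, expit(theta[np.minimum(y, K - 2)] - eta), 1.0)
    lo = np.where(y > 0, expit(theta[np.maximum(y - 1, 0)] - eta), 0.0)
    d = np.clip(hi - lo, 1e-300, None)
    return float(np.sum(np.log(d)))


def _grad_hess(params, X, y, K):
    n, p = X.shape
    theta = params[: K - 1]
    beta = params[K - 1:]
    eta = X @ beta

    a = np.where(y < K - 1, theta[np.minimum(y, K - 2)] - eta, np.inf)
    b = np.where(y > 0, theta[np.maximum(y - 1, 0)] - eta, -np.inf)
    A = expit(a)
    B = expit(b)
    D = np.clip(A - B, 1e-300, None)
    fA = np.where(np.isfinite(a), A * (1 - A), 0.0)
    fB = np.where(np.isfinite(b), B * (1 - B), 0.0)
    gA = np.where(np.isfinite(a), fA * (1 - 2 * A), 0.0)
    gB = np.where(np.isfinite(b), fB * (1 - 2 * B), 0.0)

    la = fA / D                      # dl/da
    lb = -fB / D                     # dl/db
    laa = gA / D - (fA / D) ** 2
    lbb = -gB / D - (fB / D) ** 2
    lab = fA * fB / D**2

    m = K - 1 + p
    grad = np.zeros(m)
    hess = np.zeros((m, m))

    # theta indices per observation: a involves theta[y] (if y < K-1),
    # b involves theta[y-1] (if y > 0); eta enters both with sign -1
    ia = np.where(y < K - 1, y, -1)
    ib = np.where(y > 0, y - 1, -1)

    for k in range(K - 1):
        sa = ia == k
        sb = ib == k
        grad[k] = la[sa].sum() + lb[sb].sum()
        hess[k, k] += laa[sa].sum() + lbb[sb].sum()
    # cross terms between adjacent cut points (same observation)
    both = (ia >= 0) & (ib >= 0)
    for k in range(K - 2):
        s = both & (ib == k)  # theta_k (as b) with theta_{k+1} (as a)
        hess[k, k + 1] += lab[s].sum()
        hess[k + 1, k] += lab[s].sum()

    dl_deta = -(la + lb)
    grad[K - 1:] = X.T @ dl_deta
    d2l_deta2 = laa + lbb + 2 * lab
    hess[K - 1:, K - 1:] = X.T @ (d2l_deta2[:, None] * X)
    # theta x beta cross: d2l/(dtheta_k deta) * (-1) on eta side
    for k in range(K - 1):
        sa = ia == k
        sb = ib == k
        v = np.zeros(n)
        v[sa] += laa[sa] + lab[sa]
        v[sb] += lbb[sb] + lab[sb]
        cross = -(X.T @ v)
        hess[k, K - 1:] = cross
        hess[K - 1:, k] = cross
    return grad, hess


def polr_fit(X, y, max_iter: int = 100, tol: float = 1e-10) -> PolrResult:
    """Newton-Raphson proportional-odds fit.

    Parameters: X (n x p) design without intercept (the cut points absorb
    it); y integer categories 0..K-1 with every category observed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cats = np.unique(y)
    K = len(cats)
    if K < 2:
        raise ValueError("need at least two observed categories")
    recode = {c: i for i, c in enumerate(cats)}
    y = np.vectorize(recode.get)(y)

    n, p = X.shape
    cum = np.cumsum(np.bincount(y, minlength=K))[:-1] / n
    params = np.concatenate([np.log(cum / (1 - cum)), np.zeros(p)])
    ll = _loglik(params, X, y, K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, hess = _grad_hess(params, X, y, K)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # Newton direction for a maximum: params - H^{-1} g (H negative
        # definite near the optimum); halve until the likelihood improves
        scale = 1.0
        for _ in range(40):
            cand = params - scale * step
            theta = cand[: K - 1]
            if np.all(np.diff(theta) > 0):
                ll_new = _loglik(cand, X, y, K)
                if ll_new >= ll - 1e-12:
                    break
            scale /= 2.0
        else:
            break
        moved = np.max(np.abs(cand - params))
        improved = ll_new - ll
        params, ll = cand, ll_new
        if moved < 1e-9 or (0 <= improved < tol and moved < 1e-6):
            converged = True
            break
    grad, hess = _grad_hess(params, X, y, K)
    if np.max(np.abs(grad)) < 1e-4:
        converged = True
    info = -hess
    cov = np.linalg.inv(info)
    cov_beta = cov[K - 1:, K - 1:]
    return PolrResult(params[K - 1:], params[: K - 1], cov_beta, ll, it,
                      converged)
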