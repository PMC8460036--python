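"""Combining per-cohort burden results across studies.

Two combiners: fixed-effects inverse-variance weighting (yields a pooled
estimate and SE) and a direction-aware Fisher combination (p-values only).
For the Fisher combiner each two-sided p is first converted to a one-sided
p in the consensus direction - taken as the discovery (first) study's
direction - via p/2 when concordant and 1 - p/2 when discordant; the
combined one-sided p is reported as-is by default, with optional two-sided
doubling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .datatypes import AssocResult


@dataclass
class MetaInput:
    cohort: str
    estimate: float | None
    se: float | None
    p: float
    direction: int

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if self.estimate is not None and self.estimate != 0:
            if self.direction != int(np.sign(self.estimate)):
                raise ValueError("direction inconsistent with estimate sign")

    @classmethod
    def from_assoc(cls, cohort: str, res: AssocResult) -> "MetaInput":
        return cls(cohort=cohort, estimate=res.estimate, se=res.se, p=res.p,
                   direction=res.direction or 1)


@dataclass
class MetaResult:
    method: str
    p: float
    k: int
    estimate: float | None = None
    se: float | None = None
    direction: int | None = None


def inverse_variance_meta(inputs: list) -> MetaResult:
    """Fixed-effects inverse-variance pooling of estimates."""
    if any(i.se is None or i.estimate is None for i in inputs):
        raise ValueError("inverse-variance meta needs estimates and SEs")
    if any(i.se <= 0 for i in inputs):
        raise ValueError("all SEs must be positive")
    if len(inputs) == 1:
        warnings.warn("single-study meta-analysis: passthrough")
        one = inputs[0]
        return MetaResult("ivw", one.p, 1, one.estimate, one.se, one.direction)
    w = np.array([i.se**-2 for i in inputs])
    b = np.array([i.estimate for i in inputs])
    est = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = est / se
    p = float(2 * norm.sf(abs(z)))
    return MetaResult("ivw", max(p, np.finfo(float).tiny), len(inputs), est, se,
                      int(np.sign(est)) if est != 0 else 0)


def directional_fisher(inputs: list, two_sided: bool = False) -> MetaResult:
    """Direction-aware Fisher combination of two-sided p-values."""
    if not inputs:
        raise ValueError("no inputs")
    consensus = inputs[0].direction
    one_sided = np.array([
        i.p / 2.0 if i.direction == consensus else 1.0 - i.p / 2.0
        for i in inputs
    ])
    x2 = -2.0 * np.sum(np.log(one_sided))
    p = float(chi2.sf(x2, df=2 * len(inputs)))
    if two_sided:
        p = min(2 * p, 1.0)
    return MetaResult("fisher", max(p, np.finfo(float).tiny), len(inputs),
                      direction=consensus)


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m <= 0:
        raise ValueError("number of tests must be positive")
    return alpha / m


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def select_best_model(results: list) -> AssocResult:
    """The result with the smallest p; ties break toward the more-adjusted
    model (M0 < M1 < M2 ordering)."""
    if not results:
        raise ValueError("no results")
    order = {m: i for i, m in enumerate(("M0", "M1", "M2"))}
    return min(results, key=lambda r: (r.p, -order.get(r.model, 0)))
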