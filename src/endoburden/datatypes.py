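"""Core in-memory containers shared across the pipeline.

Genotypes are held as an alt-allele dosage matrix (samples x variants) with
``numpy.nan`` marking missing calls; variant annotations, phenotypes and
expression metadata travel as pandas DataFrames with documented columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: columns of a variant annotation table (``annotations.tsv``)
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "consequence",
    "polyphen_damaging",
    "cadd_scaled",
    "af_kg_eur",
    "af_gnomad_nfe",
]

#: columns of a phenotype / covariate table (``phenotypes.tsv``)
SAMPLE_COLUMNS = [
    "sample_id",
    "status",
    "sex",
    "age",
    "center",
    "apoe_e2",
    "apoe_e4",
    "braak",
    "family_id",
    "event_time",
    "event_flag",
]

DELETERIOUS_CONSEQUENCES = frozenset(
    {"stop-gain", "stop-loss", "frameshift", "splice-donor", "splice-acceptor"}
)

ALL_CONSEQUENCES = (
    "stop-gain",
    "stop-loss",
    "frameshift",
    "splice-donor",
    "splice-acceptor",
    "missense-damaging",
    "missense-benign",
    "synonymous",
)


class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with optional GQ.

    Dosages are floats in {0, 1, 2, nan}; ``gq`` (if present) is an integer
    matrix of the same shape holding per-entry genotype qualities.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[str],
        dosage: np.ndarray,
        gq: np.ndarray | None = None,
    ):
        self.samples = np.asarray(samples, dtype=object)
        self.variants = np.asarray(variants, dtype=object)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing (nan)")
        self.dosage = dosage
        if gq is not None:
            gq = np.asarray(gq)
            if gq.shape != dosage.shape:
                raise ValueError("GQ matrix shape does not match dosage")
            if (gq < 0).any():
                raise ValueError("GQ values must be non-negative")
        self.gq = gq

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def variant_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def variant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants)}
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        variants: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        si = self.sample_index(samples) if samples is not None else slice(None)
        vi = self.variant_index(variants) if variants is not None else slice(None)
        dosage = self.dosage[si][:, vi]
        gq = self.gq[si][:, vi] if self.gq is not None else None
        new_samples = self.samples[si] if samples is not None else self.samples
        new_variants = self.variants[vi] if variants is not None else self.variants
        return GenotypeMatrix(new_samples, new_variants, dosage.copy(),
                              gq.copy() if gq is not None else None)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples.copy(),
            self.variants.copy(),
            self.dosage.copy(),
            self.gq.copy() if self.gq is not None else None,
        )

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_gq = (self.gq is None) == (other.gq is None) and (
            self.gq is None or np.array_equal(self.gq, other.gq)
        )
        return (
            np.array_equal(self.samples, other.samples)
            and np.array_equal(self.variants, other.variants)
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
            and same_gq
        )


@dataclass(frozen=True)
class GeneSet:
    """Named collection of gene ids (deduplicated, order preserved)."""

    name: str
    genes: tuple
    provenance: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        deduped = tuple(dict.fromkeys(self.genes))
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class AssocResult:
    """One association fit: effect on the log scale, Wald SE, two-sided p."""

    model: str
    phenotype: str
    estimate: float
    se: float
    p: float
    n: int
    flags: tuple = ()

    @property
    def ratio(self) -> float:
        """OR for logistic/ordinal fits, HR for proportional-hazards fits."""
        return float(np.exp(self.estimate))

    @property
    def direction(self) -> int:
        return 1 if self.estimate > 0 else (-1 if self.estimate < 0 else 0)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "phenotype": self.phenotype,
            "estimate": self.estimate,
            "se": self.se,
            "ratio": self.ratio,
            "p": self.p,
            "n": self.n,
            "direction": self.direction,
            "flags": ",".join(self.flags),
        }


class QCReport:
    """Ordered record of QC filters: thresholds and per-step removal counts."""

    def __init__(self):
        self.steps: list[dict] = []
        self.warnings: list[str] = []

    def add_step(self, name: str, *, threshold, n_in: int, n_removed: int,
                 axis: str) -> None:
        if n_removed < 0 or n_removed > n_in:
            raise ValueError("removed count inconsistent with input count")
        self.steps.append(
            {
                "step": name,
                "axis": axis,
                "threshold": threshold,
                "n_in": n_in,
                "n_removed": n_removed,
                "n_retained": n_in - n_removed,
            }
        )

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"steps": self.steps, "warnings": self.warnings}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


@dataclass
class TruthRecord:
    """Ground-truth bookkeeping for a synthetic cohort.

    Stored alongside the generated files for verification; never read by the
    analysis modules.
    """

    params: dict = field(default_factory=dict)
    sample_truth: pd.DataFrame | None = None
    variant_truth: pd.DataFrame | None = None
    gene_truth: pd.DataFrame | None = None
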