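import numpy as np
import pandas as pd
import pytest

from endoburden.config import SimConfig
from endoburden.datatypes import GeneSet, GenotypeMatrix
from endoburden.simulate import simulate_cohort


SMALL_CFG = dict(
    seed=11,
    n_samples=400,
    n_genes=30,
    n_expr_genes=12,
    n_sc_genes=400,
    n_cells_per_sample=12,
    n_sc_samples=12,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(**SMALL_CFG)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    from endoburden.cohort_io import write_cohort

    d = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_pheno(n, rng, status=None, braak=None, time=None, event=None):
    """Minimal phenotype frame with the covariate columns the models expect."""
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "status": status if status is not None
            else rng.choice(["case", "control"], n),
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(75, 6, n).round(1),
            "center": rng.choice(["A", "B"], n),
            "apoe_e2": rng.binomial(2, 0.07, n),
            "apoe_e4": rng.binomial(2, 0.2, n),
            "braak": braak if braak is not None else np.nan,
            "family_id": "NA",
            "event_time": time if time is not None else np.nan,
            "event_flag": event if event is not None else 0,
        }
    )
    for k in range(1, 11):
        df[f"PC{k}"] = rng.normal(size=n)
    df["n_rare_total"] = rng.poisson(2000, n)
    return df


def simple_geno(dosage, gq=None, prefix="S"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        [f"{prefix}{i:05d}" for i in range(n)],
        [f"v{j}" for j in range(m)],
        dosage,
        gq,
    )


@pytest.fixture
def gene_set_abc():
    return GeneSet("abc", ("A", "B", "C"))
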