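"""QC: GQ masking, missingness filters, HWE exact test, IBD, pruning, PCA."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoburden.config import SimConfig
from endoburden.datatypes import QCReport
from endoburden.qc import (
    compute_pcs,
    estimate_relatedness,
    filter_variants_basic,
    genotype_counts,
    hwe_exact_test,
    hwe_filter,
    internal_maf,
    mask_low_gq,
    prune_related,
    run_qc,
    sample_missingness_filter,
    thin_variants,
    variant_missingness_filter,
)
from endoburden.simulate import simulate_families, simulate_variant_panel

from conftest import simple_geno


def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the Levene-Haldane two-sided p-value."""
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return Fraction(1)

    def ways(h):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (factorial(n) // (factorial(h) * factorial(hom_minor)
                                 * factorial(hom_major))) * 2**h

    obs = ways(n_het)
    total = sel = 0
    for h in range(n_minor % 2, n_minor + 1, 2):
        w = ways(h)
        total += w
        if w <= obs:
            sel += w
    return Fraction(sel, total)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_symmetry_in_homozygote_classes(self):
        assert hwe_exact_test(57, 14, 50) == hwe_exact_test(50, 14, 57)

    def test_matches_oracle_on_large_deficit(self):
        # a strong heterozygote deficit: p agrees with exact enumeration
        p = hwe_exact_test(57, 14, 50)
        assert p == pytest.approx(float(hwe_oracle(57, 14, 50)), abs=1e-14)
        assert p < 1e-10

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(
            float(hwe_oracle(a, b, c)), abs=1e-10)


class TestGqMask:
    def test_threshold_semantics(self):
        geno = simple_geno([[0, 1], [2, 0]], gq=np.array([[20, 21], [99, 0]]))
        out = mask_low_gq(geno, 21)
        assert np.isnan(out.dosage[0, 0])  # GQ 20 -> missing
        assert out.dosage[0, 1] == 1       # GQ 21 kept ("below 21")
        assert np.isnan(out.dosage[1, 1])

    def test_zero_threshold_is_identity(self):
        gq = np.array([[5, 50], [0, 99]])
        geno = simple_geno([[0, 1], [2, 0]], gq=gq)
        out = mask_low_gq(geno, 0)
        assert np.array_equal(out.dosage, geno.dosage)

    def test_missing_gq_rejected(self):
        with pytest.raises(ValueError, match="GQ"):
            mask_low_gq(simple_geno([[0, 1]]), 21)


class TestBasicVariantFilters:
    def _variants(self, **over):
        base = pd.DataFrame(
            {
                "variant_id": ["v0", "v1", "v2"],
                "ref": ["A", "C", "G"],
                "alt": ["T", "G", "A"],
                "filter": ["PASS", "LowQual", "PASS"],
                "n_alt_alleles": [1, 1, 1],
            }
        )
        for k, v in over.items():
            base[k] = v
        return base

    def test_non_pass_removed(self):
        geno = simple_geno(np.zeros((2, 3)))
        kept, sub = filter_variants_basic(self._variants(), geno)
        assert list(kept["variant_id"]) == ["v0", "v2"]
        assert sub.n_variants == 2

    def test_multiallelic_rejected_with_message(self):
        geno = simple_geno(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="multi-allelic"):
            filter_variants_basic(
                self._variants(n_alt_alleles=[1, 2, 1]), geno)

    def test_all_pass_biallelic_identity(self):
        geno = simple_geno(np.zeros((2, 3)))
        kept, sub = filter_variants_basic(
            self._variants(filter=["PASS"] * 3), geno)
        assert len(kept) == 3 and sub.n_variants == 3

    def test_indels_removed(self):
        geno = simple_geno(np.zeros((2, 3)))
        kept, _ = filter_variants_basic(
            self._variants(ref=["A", "AT", "G"], filter=["PASS"] * 3), geno)
        assert "v1" not in set(kept["variant_id"])


class TestMissingnessFilters:
    def test_sample_boundary(self):
        d = np.zeros((3, 100))
        d[0, :6] = np.nan   # 6% -> removed
        d[1, :5] = np.nan   # exactly 5% -> retained
        geno = simple_geno(d)
        report = QCReport()
        kept = sample_missingness_filter(geno, 0.05, report)
        assert geno.samples[0] not in kept and geno.samples[1] in kept
        assert report.steps[0]["n_removed"] == 1

    def test_variant_boundary(self):
        d = np.zeros((100, 3))
        d[:3, 0] = np.nan   # 3% -> removed
        d[:2, 1] = np.nan   # exactly 2% -> retained
        geno = simple_geno(d)
        kept = variant_missingness_filter(geno, 0.02)
        assert "v0" not in kept and "v1" in kept and "v2" in kept

    def test_complete_data_all_retained(self):
        geno = simple_geno(np.zeros((10, 5)))
        assert len(sample_missingness_filter(geno)) == 10
        assert len(variant_missingness_filter(geno)) == 5


class TestHweFilter:
    def test_rare_only_and_strict_boundary(self, rng):
        # column 0: gross HWE violation (all hets); column 1: conforming
        n = 200
        d = np.column_stack([
            np.ones(n),
            rng.binomial(2, 0.3, n),
            np.ones(n),
        ]).astype(float)
        geno = simple_geno(d)
        controls = list(geno.samples)
        p_violation = hwe_exact_test(0, n, 0)
        assert p_violation < 0.001
        rare = np.array([True, True, False])
        kept = hwe_filter(geno, controls, rare, 0.001)
        assert "v0" not in kept          # rare + violating -> removed
        assert "v1" in kept              # rare + conforming -> kept
        assert "v2" in kept              # violating but not rare -> untouched
        # boundary: p exactly equal to the cutoff is retained
        kept2 = hwe_filter(geno, controls, rare, p_violation)
        assert "v0" in kept2


class TestRelatedness:
    @pytest.fixture(scope="class")
    @staticmethod
    def family_geno():
        cfg = SimConfig(seed=21, n_samples=600, n_genes=60,
                        variants_per_gene_mean=10, n_families=30,
                        sibship_size=2, family_capacity=200)
        panel = simulate_variant_panel(cfg)
        rng = np.random.default_rng(5)
        panel["af_true"] = rng.uniform(0.1, 0.5, len(panel))
        return simulate_families(cfg, panel)

    def test_duplicate_pihat_near_one(self, family_geno):
        geno, _, _ = family_geno
        dup = geno.subset(samples=list(geno.samples[:20]))
        d = np.vstack([dup.dosage, dup.dosage[:1]])
        from endoburden.datatypes import GenotypeMatrix

        g2 = GenotypeMatrix(list(dup.samples) + ["copy"], dup.variants, d)
        rel = estimate_relatedness(g2)
        row = rel[(rel.sample_i == dup.samples[0]) & (rel.sample_j == "copy")]
        assert row["pi_hat"].iloc[0] >= 0.95

    def test_parent_offspring_band(self, family_geno):
        geno, _, samples = family_geno
        rel = estimate_relatedness(geno)
        roles = samples.set_index("sample_id")
        fam = roles["family_id"]
        role = roles["role"]
        same_fam = fam[rel.sample_i].to_numpy() == fam[rel.sample_j].to_numpy()
        parent_i = role[rel.sample_i].isin(["father", "mother"]).to_numpy()
        parent_j = role[rel.sample_j].isin(["father", "mother"]).to_numpy()
        po = same_fam & (parent_i ^ parent_j)
        assert po.sum() >= 50
        # genome-shared fraction pi-hat is 0.5 for parent-offspring;
        # the kinship coefficient pi-hat/2 recovers the pedigree 0.25
        assert rel.loc[po, "pi_hat"].between(0.4, 0.6).mean() > 0.9
        assert abs(rel.loc[po, "pi_hat"].mean() / 2 - 0.25) < 0.03

    def test_unrelated_near_zero(self, family_geno):
        geno, _, samples = family_geno
        rel = estimate_relatedness(geno)
        fam = samples.set_index("sample_id")["family_id"]
        across = fam[rel.sample_i].to_numpy() != fam[rel.sample_j].to_numpy()
        assert abs(rel.loc[across, "pi_hat"].mean() / 2) < 0.02
        assert (rel.loc[across, "pi_hat"] <= 0.1).mean() > 0.9

    def test_symmetric_under_sample_reordering(self, family_geno):
        geno, _, _ = family_geno
        sub = geno.subset(samples=list(geno.samples[:8]))
        rev = geno.subset(samples=list(geno.samples[:8][::-1]))
        a = estimate_relatedness(sub)
        b = estimate_relatedness(rev)
        key = lambda df: df.assign(
            lo=np.minimum(df.sample_i, df.sample_j),
            hi=np.maximum(df.sample_i, df.sample_j),
        ).set_index(["lo", "hi"])["pi_hat"].sort_index()
        assert np.allclose(key(a), key(b), atol=1e-12)


class TestPruneRelated:
    def _rel(self, pairs):
        return pd.DataFrame(
            [{"sample_i": a, "sample_j": b, "pi_hat": p} for a, b, p in pairs]
        )

    def test_trio_keeps_one(self):
        rel = self._rel([("f", "m", 0.01), ("f", "c", 0.5), ("m", "c", 0.5)])
        assert len(prune_related(rel)) == 1

    def test_unrelated_all_kept(self):
        rel = self._rel([("a", "b", 0.01), ("b", "c", 0.02), ("a", "c", 0.0)])
        assert sorted(prune_related(rel)) == ["a", "b", "c"]

    def test_duplicate_keeps_lower_missingness(self):
        rel = self._rel([("a", "b", 0.99)])
        kept = prune_related(rel, missing_rate={"a": 0.04, "b": 0.01})
        assert kept == ["b"]


class TestPca:
    def test_two_populations_separate_on_pc1(self, rng):
        n, m = 120, 300
        af1, af2 = rng.uniform(0.1, 0.4, m), rng.uniform(0.3, 0.6, m)
        d = np.vstack([
            rng.binomial(2, af1, (n // 2, m)),
            rng.binomial(2, af2, (n // 2, m)),
        ]).astype(float)
        geno = simple_geno(d)
        pcs = compute_pcs(geno, k=10)
        group = np.repeat([0.0, 1.0], n // 2)
        r = np.corrcoef(pcs["PC1"], group)[0, 1]
        assert abs(r) > 0.9

    def test_orthonormal_columns(self, rng):
        d = rng.binomial(2, 0.3, (50, 80)).astype(float)
        pcs = compute_pcs(simple_geno(d), k=5).to_numpy()
        assert np.allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_degenerate_rows_no_nan(self):
        d = np.tile([0.0, 1.0, 2.0, 0.0], (6, 1))
        with pytest.warns(UserWarning):
            pcs = compute_pcs(simple_geno(d), k=3)
        assert not pcs.isna().any().any()


class TestQcChain:
    def test_rerun_is_noop_and_order_recorded(self, small_cohort):
        v1, g1, r1 = run_qc(small_cohort.panel, small_cohort.geno,
                            small_cohort.pheno)
        steps = [s["step"] for s in r1.steps]
        assert steps[:4] == ["vqsr_biallelic_snv", "gq_mask",
                             "sample_missingness", "variant_missingness"]
        assert "hwe_controls" in steps
        v2, g2, r2 = run_qc(v1, g1, small_cohort.pheno)
        assert g2.n_samples == g1.n_samples
        assert g2.n_variants == g1.n_variants

    def test_internal_maf_folds(self):
        geno = simple_geno(np.array([[2.0, 0.0], [2.0, 0.0], [1.0, 1.0]]))
        maf = internal_maf(geno)
        assert maf[0] == pytest.approx(1 / 6)  # alt freq 5/6 folds to 1/6
        assert maf[1] == pytest.approx(1 / 6)

    def test_thin_variants_one_per_window(self):
        pos = pd.DataFrame({"chrom": ["1"] * 4 + ["2"],
                            "pos": [100, 200, 100_200, 100_300, 100]})
        mask = thin_variants(pos, window=100_000)
        assert mask.tolist() == [True, False, True, False, True]

    def test_genotype_counts(self):
        geno = simple_geno(np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 2.0]]))
        counts = genotype_counts(geno)
        assert counts[0].tolist() == [1, 1, 1]
        assert counts[1].tolist() == [0, 1, 1]
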