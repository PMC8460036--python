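"""Burden scoring, residualization, and the nested association models."""

import numpy as np
import pandas as pd
import pytest

from endoburden.burden import (
    burden_score,
    cox_burden_test,
    logistic_burden_test,
    model_design,
    ordinal_burden_test,
    residualize,
)
from endoburden.glmm import glmm_burden_test, nearest_psd

from conftest import make_pheno, simple_geno


class TestBurdenScore:
    def test_basic_fraction(self):
        geno = simple_geno(np.array([[0.0, 1.0, 2.0]]))
        assert burden_score(geno, geno.variants).iloc[0] == pytest.approx(0.5)

    def test_missing_excluded_from_denominator(self):
        geno = simple_geno(np.array([[1.0, np.nan, 2.0]]))
        assert burden_score(geno, geno.variants).iloc[0] == pytest.approx(0.75)

    def test_all_reference_zero(self):
        geno = simple_geno(np.zeros((3, 4)))
        assert (burden_score(geno, geno.variants) == 0).all()

    def test_all_missing_sample_flagged(self):
        geno = simple_geno(np.array([[np.nan, np.nan], [1.0, 0.0]]))
        raw = burden_score(geno, geno.variants)
        assert np.isnan(raw.iloc[0]) and raw.iloc[1] == pytest.approx(0.25)

    def test_invariant_to_variant_order_and_zero_weight_duplicates(self):
        geno = simple_geno(np.array([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0]]))
        a = burden_score(geno, ["v0", "v1", "v2"], [1.0, 1.0, 1.0])
        b = burden_score(geno, ["v2", "v0", "v1"], [1.0, 1.0, 1.0])
        c = burden_score(geno, ["v0", "v1", "v2", "v0"], [1.0, 1.0, 1.0, 0.0])
        assert np.allclose(a, b) and np.allclose(a, c)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            burden_score(simple_geno(np.zeros((2, 2))), [])


class TestResidualize:
    def _inputs(self, rng, n=200):
        raw = pd.Series(rng.random(n), index=[f"S{i:05d}" for i in range(n)])
        nrt = pd.Series(rng.poisson(2000, n), index=raw.index)
        pcs = pd.DataFrame(rng.normal(size=(n, 10)), index=raw.index,
                           columns=[f"PC{i + 1}" for i in range(10)])
        return raw, nrt, pcs

    def test_residuals_orthogonal_to_covariates(self, rng):
        raw, nrt, pcs = self._inputs(rng)
        resid = residualize(raw, nrt, pcs)
        assert abs(resid.mean()) < 1e-10
        X = np.column_stack([nrt, pcs])
        for j in range(X.shape[1]):
            assert abs(np.corrcoef(resid, X[:, j])[0, 1]) < 1e-8

    def test_linear_function_of_count_vanishes(self, rng):
        raw, nrt, pcs = self._inputs(rng)
        raw = 0.1 + 0.001 * nrt
        resid = residualize(raw, nrt, pcs)
        assert np.abs(resid).max() < 1e-8

    def test_rank_deficiency_warns(self, rng):
        raw, nrt, pcs = self._inputs(rng)
        pcs["PC10"] = pcs["PC1"]  # collinear column
        with pytest.warns(UserWarning, match="rank"):
            residualize(raw, nrt, pcs)


def _scored_pheno(rng, n=600, beta=0.8, kind="ad"):
    """Phenotypes with a known burden effect on the requested outcome."""
    z = rng.normal(size=n)
    pheno = make_pheno(n, rng)
    if kind == "ad":
        from scipy.special import expit

        pheno["status"] = np.where(
            rng.random(n) < expit(beta * z), "case", "control")
    elif kind == "braak":
        cuts = np.array([-2.5, -1.5, -0.5, 0.3, 1.0, 1.8])
        latent = beta * z + rng.logistic(size=n)
        pheno["braak"] = np.searchsorted(cuts, latent).astype(float)
    elif kind == "surv":
        rate = 0.05 * np.exp(beta * z)
        t = rng.exponential(1 / rate)
        c = np.quantile(t, 0.7)
        pheno["event_time"] = np.minimum(t, c) + 0.01
        pheno["event_flag"] = (t <= c).astype(int)
    resid = pd.Series(z, index=pheno["sample_id"].to_numpy())
    return resid, pheno


class TestLogistic:
    def test_recovers_effect_and_m_nesting(self, rng):
        resid, pheno = _scored_pheno(rng, n=1500, beta=np.log(1.5))
        for model in ("M0", "M1", "M2"):
            res = logistic_burden_test(resid, pheno, model)
            assert res.p < 0.01
            assert abs(res.estimate - np.log(1.5)) < 3 * res.se
        d0 = model_design(pheno.set_index("sample_id"), "M0").columns
        d1 = model_design(pheno.set_index("sample_id"), "M1").columns
        d2 = model_design(pheno.set_index("sample_id"), "M2").columns
        assert set(d0) < set(d1) < set(d2)
        assert {"age", "sex"} <= set(d1) - set(d0)
        assert {"apoe_e2", "apoe_e4"} == set(d2) - set(d1)

    def test_label_flip_negates_estimate(self, rng):
        resid, pheno = _scored_pheno(rng, n=800, beta=0.5)
        res = logistic_burden_test(resid, pheno, "M0")
        flipped = pheno.assign(
            status=pheno["status"].map({"case": "control", "control": "case"}))
        res2 = logistic_burden_test(resid, flipped, "M0")
        assert res2.estimate == pytest.approx(-res.estimate, abs=1e-6)
        assert res2.direction == -res.direction

    def test_mci_excluded(self, rng):
        resid, pheno = _scored_pheno(rng, n=400, beta=0.0)
        pheno.loc[:49, "status"] = "MCI"
        res = logistic_burden_test(resid, pheno, "M0")
        assert res.n == 350

    def test_constant_burden_rejected(self, rng):
        _, pheno = _scored_pheno(rng, n=100, beta=0.0)
        const = pd.Series(0.3, index=pheno["sample_id"].to_numpy())
        with pytest.raises(ValueError, match="variation"):
            logistic_burden_test(const, pheno, "M0")

    def test_separation_flagged_with_lrt_fallback(self, rng):
        n = 60
        pheno = make_pheno(n, rng)
        z = np.linspace(-2, 2, n)
        pheno["status"] = np.where(z > 0, "case", "control")
        resid = pd.Series(z, index=pheno["sample_id"].to_numpy())
        res = logistic_burden_test(resid, pheno, "M0")
        assert "separation_lrt_p" in res.flags
        assert 0 < res.p < 0.05


class TestOrdinal:
    def test_two_categories_match_logistic(self, rng):
        resid, pheno = _scored_pheno(rng, n=800, beta=0.6, kind="braak")
        pheno["braak"] = (pheno["braak"] >= 3).astype(float)
        ordp = ordinal_burden_test(resid, pheno, "M1")
        pheno2 = pheno.assign(
            status=np.where(pheno["braak"] == 1, "case", "control"))
        logp = logistic_burden_test(resid, pheno2, "M1")
        assert ordp.estimate == pytest.approx(logp.estimate, abs=1e-5)

    def test_recovers_effect(self, rng):
        resid, pheno = _scored_pheno(rng, n=1200, beta=0.5, kind="braak")
        res = ordinal_burden_test(resid, pheno, "M0")
        assert abs(res.estimate - 0.5) < 3 * res.se
        assert res.p < 0.01

    def test_reversed_order_negates(self, rng):
        resid, pheno = _scored_pheno(rng, n=600, beta=0.5, kind="braak")
        res = ordinal_burden_test(resid, pheno, "M0")
        rev = pheno.assign(braak=6 - pheno["braak"])
        res2 = ordinal_burden_test(resid, rev, "M0")
        assert res2.estimate == pytest.approx(-res.estimate, abs=1e-4)

    def test_matches_generic_likelihood_optimizer(self, rng):
        # independent route: statsmodels OrderedModel (numerical derivatives)
        import warnings

        from statsmodels.miscmodels.ordinal_model import OrderedModel

        resid, pheno = _scored_pheno(rng, n=700, beta=0.5, kind="braak")
        res = ordinal_burden_test(resid, pheno, "M1")
        df = pheno.set_index("sample_id")
        X = pd.concat([resid.rename("burden"),
                       model_design(df, "M1")], axis=1)
        X = X.loc[:, X.std() > 0]
        endog = pd.Categorical(df["braak"].astype(int), ordered=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = OrderedModel(endog, X, distr="logit").fit(
                method="lbfgs", pgtol=1e-12, factr=1.0, maxiter=5000, disp=0)
        assert res.estimate == pytest.approx(fit.params["burden"], abs=1e-6)
        assert res.se == pytest.approx(fit.bse["burden"], rel=1e-4)

    def test_single_category_rejected(self, rng):
        resid, pheno = _scored_pheno(rng, n=100, beta=0.0, kind="braak")
        pheno["braak"] = 3.0
        with pytest.raises(ValueError, match="categories"):
            ordinal_burden_test(resid, pheno, "M0")


def efron_partial_loglik(beta_vec, time, event, X):
    """Brute-force Efron partial log-likelihood (oracle)."""
    eta = X @ beta_vec
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        risk = time >= t
        d = tied.sum()
        ll += eta[tied].sum()
        s_risk = theta[risk].sum()
        s_tied = theta[tied].sum()
        for ell in range(d):
            ll -= np.log(s_risk - ell / d * s_tied)
    return ll


class TestCox:
    def test_matches_efron_grid_oracle_with_ties(self, rng):
        time = np.array([2.0, 2.0, 2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        x = np.array([1.2, -0.3, 0.5, 0.8, -1.1, 0.0, 0.4, -0.7, 1.5, -0.2])
        grid = np.linspace(-3, 3, 60001)
        ll = [efron_partial_loglik(np.array([b]), time, event, x[:, None])
              for b in grid]
        beta_oracle = grid[int(np.argmax(ll))]

        pheno = make_pheno(10, rng)
        pheno["event_time"] = time
        pheno["event_flag"] = event
        pheno["center"] = "A"
        for k in range(1, 11):
            pheno[f"PC{k}"] = 0.0
        resid = pd.Series(x, index=pheno["sample_id"].to_numpy())
        res = cox_burden_test(resid, pheno, "M0")
        assert res.estimate == pytest.approx(beta_oracle, abs=1e-4)

    def test_two_group_hazard_ratio_recovery(self, rng):
        hits, logs = 0, []
        reps = 30
        for _ in range(reps):
            n = 500
            pheno = make_pheno(n, rng)
            g = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1 / (0.05 * np.exp(np.log(2) * g)))
            pheno["event_time"] = t + 0.01
            pheno["event_flag"] = 1
            resid = pd.Series(g, index=pheno["sample_id"].to_numpy())
            res = cox_burden_test(resid, pheno, "M0")
            hits += 1.7 <= res.ratio <= 2.35
            logs.append(res.estimate)
        assert hits / reps >= 0.8
        assert abs(np.mean(logs) - np.log(2)) < 0.05

    def test_age_never_a_covariate(self, rng):
        resid, pheno = _scored_pheno(rng, n=300, beta=0.4, kind="surv")
        for model in ("M0", "M1", "M2"):
            X = model_design(pheno.set_index("sample_id"), model,
                             include_age=False)
            assert "age" not in X.columns

    def test_group_swap_negates(self, rng):
        resid, pheno = _scored_pheno(rng, n=400, beta=0.6, kind="surv")
        res = cox_burden_test(resid, pheno, "M0")
        res2 = cox_burden_test(-resid, pheno, "M0")
        assert res2.estimate == pytest.approx(-res.estimate, abs=1e-8)

    def test_no_events_rejected(self, rng):
        resid, pheno = _scored_pheno(rng, n=100, beta=0.0, kind="surv")
        pheno["event_flag"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_burden_test(resid, pheno, "M0")


class TestGlmm:
    def test_zero_kinship_reduces_to_logistic(self, rng):
        resid, pheno = _scored_pheno(rng, n=300, beta=0.5)
        ids = pheno["sample_id"].to_numpy()
        kin = pd.DataFrame(np.zeros((300, 300)), index=ids, columns=ids)
        g = glmm_burden_test(resid, pheno, kin, "M1")
        l = logistic_burden_test(resid, pheno, "M1")
        assert g.estimate == pytest.approx(l.estimate, abs=1e-4)
        assert g.se == pytest.approx(l.se, rel=1e-3)

    def test_family_estimate_close_to_independent_fit(self, rng):
        # mirrors the observation that kinship adjustment shifts the
        # estimate only slightly on sibship data
        from endoburden.config import SimConfig
        from endoburden.datatypes import GeneSet
        from endoburden.simulate import (
            simulate_families, simulate_phenotypes, simulate_variant_panel)

        cfg = SimConfig(seed=31, n_samples=600, n_genes=30, n_families=60,
                        sibship_size=2, family_capacity=300,
                        burden_logOR=np.log(1.4))
        panel = simulate_variant_panel(cfg)
        geno, kin, fam = simulate_families(cfg, panel)
        gs = GeneSet("all", tuple(panel["gene_id"].unique()))
        pheno, truth = simulate_phenotypes(
            geno, panel, gs, cfg, family_ids=fam["family_id"].tolist())
        z = pd.Series(truth.sample_truth["true_burden_z"].to_numpy(),
                      index=geno.samples)
        g = glmm_burden_test(z, pheno, kin, "M2")
        l = logistic_burden_test(z, pheno, "M2")
        assert abs(g.estimate - l.estimate) < 0.5 * l.se
        assert g.se >= 0.95 * l.se  # mixed model never overstates precision

    def test_non_psd_kinship_repaired(self):
        k = np.array([[0.5, 0.8], [0.8, 0.5]])
        with pytest.warns(UserWarning, match="PSD"):
            fixed = nearest_psd(k)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
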