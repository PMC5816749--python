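"""REML engine against dense-matrix and closed-form oracles."""

import numpy as np
import pytest

from _oracles import anova_sire_variance, dense_reml_negll
from conftest import make_toy_conc
from pkherit import (
    LegendreBasis,
    VarianceSpec,
    build_pk_design,
    build_rr_design,
    fit_reml,
    heritability_curve,
    heritability_from_fit,
    likelihood_ratio_test,
    reml_neg_loglik,
    simulate_response,
    simulate_sire_trait,
)
from pkherit.reml import natural_names, natural_to_varmodel, untransform


def _rand_theta(rng, design, spec):
    return rng.normal(0.0, 0.5, len(natural_names(design, spec)))


class TestLikelihoodOracle:
    @pytest.mark.parametrize("nr,ar1", [(0, False), (1, False), (0, True), (1, True)])
    def test_het_hour_structures_match_dense_formula(self, toy_conc, nr, ar1):
        rng = np.random.default_rng(nr + 10 * ar1)
        d = build_rr_design(toy_conc, nf=2, nr=nr)
        spec = VarianceSpec("het_hour", ar1=ar1)
        for _ in range(3):
            theta = _rand_theta(rng, d, spec)
            vm = natural_to_varmodel(untransform(theta, d, spec), d, spec)
            assert reml_neg_loglik(theta, d, spec) == pytest.approx(
                dense_reml_negll(vm, d, spec), abs=1e-8)

    def test_weighted_structure_matches_dense_formula(self):
        rng = np.random.default_rng(0)
        df = simulate_sire_trait(5, 3, 0.3, 0.1, 1.0, n_batches=2, seed=1)
        df["weight"] = rng.uniform(0.2, 1.0, len(df))
        d = build_pk_design(df, "y")
        spec = VarianceSpec("weighted")
        for _ in range(3):
            theta = _rand_theta(rng, d, spec)
            vm = natural_to_varmodel(untransform(theta, d, spec), d, spec)
            assert reml_neg_loglik(theta, d, spec) == pytest.approx(
                dense_reml_negll(vm, d, spec), abs=1e-8)

    def test_ols_degenerate_limit(self):
        """No random effects, unit weights: restricted likelihood equals
        the closed form (n-p) log s2 / 2 + log|X'X|/2 + RSS/(2 s2)."""
        rng = np.random.default_rng(3)
        df = simulate_sire_trait(4, 3, 0.0, 0.0, 1.0, seed=3)
        d = build_pk_design(df, "y", weight_policy="uniform", include_sire=False)
        assert d.Z.shape[1] == 0
        spec = VarianceSpec("weighted")
        s2 = 1.7
        X, y = d.X, d.y
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        n, p = X.shape
        _, ldXX = np.linalg.slogdet(X.T @ X)
        closed = 0.5 * ((n - p) * np.log(s2) + ldXX + rss / s2)
        assert reml_neg_loglik(np.array([np.log(s2)]), d, spec) == pytest.approx(
            closed, abs=1e-10)

    def test_ar1_rho_zero_equals_independent(self, toy_conc):
        d = build_rr_design(toy_conc, nf=2, nr=0)
        spec_ind = VarianceSpec("het_hour")
        spec_ar = VarianceSpec("het_hour", ar1=True)
        rng = np.random.default_rng(8)
        theta = _rand_theta(rng, d, spec_ind)
        theta_ar = np.append(theta, 0.0)  # atanh(0) = 0
        assert reml_neg_loglik(theta_ar, d, spec_ar) == pytest.approx(
            reml_neg_loglik(theta, d, spec_ind), abs=1e-10)


class TestFitting:
    def test_balanced_one_way_matches_anova(self):
        df = simulate_sire_trait(10, 8, sigma2_sire=0.3, sigma2_e=1.0, seed=3)
        d = build_pk_design(df, "y", weight_policy="uniform")
        fit = fit_reml(d, VarianceSpec("weighted"))
        sire_idx = df["sire_id"].to_numpy()
        s2s_anova, _ = anova_sire_variance(df["y"].to_numpy(), sire_idx, 8)
        assert fit.varmodel.sigma2_sire == pytest.approx(s2s_anova, abs=1e-6)

    def test_scale_equivariance(self):
        df = simulate_sire_trait(8, 6, 0.4, 0.2, 1.0, n_batches=3, seed=5)
        d = build_pk_design(df, "y", weight_policy="uniform")
        fit1 = fit_reml(d, VarianceSpec("weighted"))
        d2 = d.replace_y(2.0 * d.y)
        fit2 = fit_reml(d2, VarianceSpec("weighted"))
        assert np.allclose(fit2.natural, 4.0 * fit1.natural, rtol=1e-4, atol=1e-8)
        h1 = heritability_from_fit(fit1).h2
        h2 = heritability_from_fit(fit2).h2
        assert h2 == pytest.approx(h1, rel=1e-4)

    def test_weight_rescaling_contract(self):
        """weights * c rescales sigma2_e by 1/c, leaving var(e_i) =
        sigma2_e / w_i and the other components invariant."""
        rng = np.random.default_rng(6)
        df = simulate_sire_trait(8, 6, 0.4, 0.0, 1.0, seed=6)
        df["weight"] = rng.uniform(0.3, 1.0, len(df))
        d = build_pk_design(df, "y")
        fit1 = fit_reml(d, VarianceSpec("weighted"))
        df2 = df.assign(weight=df["weight"] * 5.0)
        fit2 = fit_reml(build_pk_design(df2, "y"), VarianceSpec("weighted"))
        s2e_1 = float(fit1.varmodel.sigma2_e)
        s2e_2 = float(fit2.varmodel.sigma2_e)
        # var(e_i) = sigma2_e / w_i is invariant, so sigma2_e scales with c
        assert s2e_2 / 5.0 == pytest.approx(s2e_1, rel=1e-4)
        assert fit2.varmodel.sigma2_sire == pytest.approx(
            fit1.varmodel.sigma2_sire, rel=1e-3, abs=1e-8)

    def test_basis_normalization_invariance(self):
        """Normalized vs unnormalized Legendre basis changes S but leaves
        the heritability curve t_t S t_t'-based h2 unchanged."""
        hours = (1.0, 4.0, 12.0, 24.0)
        df = make_toy_conc(n_sires=20, n_progeny=6, hours=hours,
                           n_batches=3, seed=4)
        spec = VarianceSpec("het_hour")
        gen_basis = LegendreBasis(order=2, t_min=1.0, t_max=24.0)
        d_gen = build_rr_design(df, nf=2, nr=1, basis=gen_basis)
        vm = natural_to_varmodel(
            np.array([0.3, 0.05, 0.1, 0.1, 0.8, 0.6, 0.5, 0.4]), d_gen, spec)
        beta = np.zeros(d_gen.X.shape[1]); beta[0] = 4.0
        y = simulate_response(d_gen, vm, beta, np.random.default_rng(2))
        df = df.assign(conc_ug_per_ml=y - y.min() + 0.1)
        h2_curves = []
        for normalized in (True, False):
            basis = LegendreBasis(order=2, t_min=1.0, t_max=24.0,
                                  normalized=normalized)
            d = build_rr_design(df, nf=2, nr=1, basis=basis)
            fit = fit_reml(d, spec, multi_start=2)
            h2_curves.append([e.h2 for e in heritability_curve(fit)])
        assert np.allclose(h2_curves[0], h2_curves[1], atol=1e-6)

    def test_rr_component_recovery(self):
        """Random-regression variance components are recovered within 3
        Monte-Carlo SEs over 20 replicates (100 sires x 10 progeny)."""
        df = make_toy_conc(n_sires=100, n_progeny=10,
                           hours=(0.5, 2, 6, 24, 48), n_batches=8, seed=0)
        d = build_rr_design(df, nf=2, nr=0)
        spec = VarianceSpec("het_hour")
        true_S = np.array([[0.3]])
        true_b = 0.1
        true_e = np.array([1.0, 0.8, 0.6, 0.5, 0.4])
        vm = natural_to_varmodel(
            np.concatenate([[0.3], [0.1], true_e]), d, spec)
        beta = np.zeros(d.X.shape[1]); beta[0] = 5.0
        rng = np.random.default_rng(12)
        ests = []
        for _ in range(20):
            y = simulate_response(d, vm, beta, rng)
            fit = fit_reml(d.replace_y(y), spec, polish=False)
            ests.append(fit.natural)
        ests = np.asarray(ests)
        truth = np.concatenate([[0.3], [0.1], true_e])
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(20)
        assert np.all(np.abs(ests.mean(axis=0) - truth) <= 3 * mc_se + 1e-9)


class TestLRT:
    def test_identical_fits_give_stat_zero(self):
        df = simulate_sire_trait(6, 4, 0.3, 0.0, 1.0, seed=2)
        d = build_pk_design(df, "y", weight_policy="uniform")
        fit = fit_reml(d, VarianceSpec("weighted"))
        fit2 = fit_reml(d, VarianceSpec("weighted"))
        fit2.n_params += 1  # nominal nesting for the df computation
        stat, df_, p = likelihood_ratio_test(fit, fit2)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_chi2_reference_value(self):
        from scipy import stats as ss
        assert ss.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_sire_term_detected_when_strong(self):
        df = simulate_sire_trait(30, 10, sigma2_sire=0.5, sigma2_e=0.5, seed=9)
        d_full = build_pk_design(df, "y", weight_policy="uniform")
        d_red = build_pk_design(df, "y", weight_policy="uniform",
                                include_sire=False)
        full = fit_reml(d_full, VarianceSpec("weighted"))
        red = fit_reml(d_red, VarianceSpec("weighted"))
        stat, dof, p = likelihood_ratio_test(red, full, boundary=True)
        assert dof == 1
        assert p < 1e-6
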