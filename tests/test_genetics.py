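"""Heritability transforms, BLUP properties, and curve predictions."""

import numpy as np
import pytest

from conftest import make_toy_conc
from pkherit import (
    LegendreBasis,
    VarianceSpec,
    additive_from_sire,
    build_pk_design,
    build_rr_design,
    fit_reml,
    heritability_curve,
    heritability_from_fit,
    heritability_scalar,
    predict_sire_curves,
    simulate_sire_trait,
    sire_variance_at_time,
)
from pkherit.reml import natural_to_varmodel, simulate_response


class TestScalarFormulas:
    @pytest.mark.parametrize("s2s,expected", [(0.0, 0.0), (0.05, 0.20), (1.25, 5.0)])
    def test_additive_is_four_times_sire(self, s2s, expected):
        assert additive_from_sire(s2s) == pytest.approx(expected, abs=1e-12)

    def test_negative_sire_variance_rejected(self):
        with pytest.raises(ValueError):
            additive_from_sire(-0.1)

    def test_h2_examples(self):
        assert heritability_scalar(0.0, 0.1, 0.9).h2 == 0.0
        est = heritability_scalar(0.05, 0.10, 0.85)
        assert est.sigma2_a == pytest.approx(0.20)
        assert est.h2 == pytest.approx(0.20, abs=1e-12)

    def test_h2_above_one_is_flagged_not_clipped(self):
        est = heritability_scalar(0.5, 0.0, 0.5)
        assert est.h2 == pytest.approx(2.0)
        assert est.exceeds_one

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            heritability_scalar(0.0, 0.0, 0.0)

    def test_contains_zero_flag_uses_se_band(self):
        assert heritability_scalar(0.1, 0.1, 0.8, se=0.5).contains_zero
        assert not heritability_scalar(0.4, 0.1, 0.5, se=0.1).contains_zero


class TestSireVarianceAtTime:
    def test_identity_quadratic_form(self):
        assert sire_variance_at_time(np.eye(2), [1.0, 0.0]) == pytest.approx(1.0)

    def test_normalized_basis_midpoint(self):
        S = np.array([[0.04, 0.01], [0.01, 0.02]])
        b = LegendreBasis(order=1, t_min=0.0, t_max=10.0)
        t_row = b.row(5.0)  # x = 0 -> (sqrt(1/2), 0)
        assert t_row == pytest.approx([np.sqrt(0.5), 0.0], abs=1e-12)
        assert sire_variance_at_time(S, t_row) == pytest.approx(0.02, abs=1e-12)

    def test_intercept_only_constant_across_time(self):
        b = LegendreBasis(order=0, t_min=0.5, t_max=48.0)
        vals = [sire_variance_at_time([[0.3]], b.row(t)) for t in (0.5, 7, 48)]
        assert np.ptp(vals) < 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sire_variance_at_time(np.eye(3), [1.0, 0.0])


@pytest.fixture(scope="module")
def rr_fit():
    """A seeded intercept-only random-regression fit on synthetic data."""
    df = make_toy_conc(n_sires=15, n_progeny=6, hours=(1, 4, 12, 24.0),
                       n_batches=3, seed=5)
    d = build_rr_design(df, nf=2, nr=0)
    spec = VarianceSpec("het_hour")
    vm = natural_to_varmodel(np.array([0.25, 0.1, 0.9, 0.7, 0.5, 0.4]), d, spec)
    beta = np.zeros(d.X.shape[1]); beta[0] = 4.0
    y = simulate_response(d, vm, beta, np.random.default_rng(7))
    return fit_reml(d.replace_y(y), spec)


class TestCurves:
    def test_intercept_only_h2_varies_only_with_residual(self, rr_fit):
        ests = heritability_curve(rr_fit)
        s2s = [e.sigma2_sire for e in ests]
        assert np.ptp(s2s) < 1e-10  # constant sire variance across time
        s2e = np.array([e.sigma2_e for e in ests])
        h2 = np.array([e.h2 for e in ests])
        assert np.argmax(h2) == np.argmin(s2e)

    def test_unknown_hour_is_named_in_error(self, rr_fit):
        with pytest.raises(ValueError, match="7"):
            heritability_curve(rr_fit, times_h=[7.0])

    def test_matches_scalar_formula_row_by_row(self, rr_fit):
        for e in heritability_curve(rr_fit):
            again = heritability_scalar(e.sigma2_sire, e.sigma2_batch, e.sigma2_e)
            assert e.h2 == pytest.approx(again.h2, abs=1e-12)

    def test_sire_blup_intercepts_sum_near_zero(self, rr_fit):
        assert abs(rr_fit.blup_sire[:, 0].sum()) < 1e-6 * max(
            1.0, np.abs(rr_fit.blup_sire).max())

    def test_population_and_deviation_curves_shapes(self, rr_fit):
        times, pop, dev = predict_sire_curves(rr_fit)
        assert pop.shape == times.shape
        assert dev.shape == (15, len(times))

    def test_boundary_sire_variance_shrinks_blups_to_zero(self):
        df = simulate_sire_trait(50, 4, sigma2_sire=0.0, sigma2_e=1.0, seed=3)
        d = build_pk_design(df, "y", weight_policy="uniform")
        fit = fit_reml(d, VarianceSpec("weighted"))
        if fit.varmodel.sigma2_sire < 1e-6:
            assert np.max(np.abs(fit.blup_sire)) < 1e-3


class TestHandSolvedMME:
    def test_two_sire_blups_match_hand_solution(self):
        """y = mu + sire + e, 2 sires x 2 progeny; at fixed variance ratio
        the 2x2 mixed-model equations have a closed-form solution."""
        y = np.array([1.0, 2.0, 3.0, 5.0])
        s2s, s2e = 0.5, 1.0
        # MME: [[X'X, X'Z],[Z'X, Z'Z + (s2e/s2s) I]] [mu, u] = [X'y, Z'y]
        lam = s2e / s2s
        A = np.array([
            [4.0, 2.0, 2.0],
            [2.0, 2.0 + lam, 0.0],
            [2.0, 0.0, 2.0 + lam],
        ])
        rhs = np.array([y.sum(), y[:2].sum(), y[2:].sum()])
        mu, u1, u2 = np.linalg.solve(A, rhs)

        import pandas as pd
        df = pd.DataFrame({
            "animal_id": list("abcd"),
            "sire_id": ["S1", "S1", "S2", "S2"],
            "y": y, "weight": 1.0,
        })
        d = build_pk_design(df, "y", weight_policy="uniform")
        from pkherit.reml import VarianceModel, _core
        vm = VarianceModel(S=np.array([[s2s]]), sigma2_batch=None,
                           sigma2_e=s2e, rho=None, spec=VarianceSpec("weighted"))
        _, cho, sol, p, q = _core(vm, d, VarianceSpec("weighted"))
        assert sol[0] == pytest.approx(mu, abs=1e-8)
        assert sol[1] == pytest.approx(u1, abs=1e-8)
        assert sol[2] == pytest.approx(u2, abs=1e-8)


class TestDeltaMethod:
    def test_scalar_se_positive_and_finite(self):
        df = simulate_sire_trait(30, 8, sigma2_sire=0.3, sigma2_batch=0.1,
                                 sigma2_e=0.8, n_batches=5, seed=8)
        d = build_pk_design(df, "y", weight_policy="uniform")
        fit = fit_reml(d, VarianceSpec("weighted"))
        est = heritability_from_fit(fit)
        assert np.isfinite(est.se) and est.se > 0
        assert 0 <= est.h2 < 2
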