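"""Ridge-BLUP and Bayesian whole-genome regression contracts.

The samplers are checked against independent oracles: the ridge closed form
against a generic numerical optimizer, the Bayesian ridge (with variances
frozen) against the fixed-penalty ridge solution it is conjugate to, and
BayesB with no point mass against BayesA.
"""

import numpy as np
import pytest
from scipy import optimize

from gpbench.datatypes import AlignmentError, DegenerateTraitError
from gpbench.linear import (
    BayesPrior,
    fit_bayesian_regression,
    fit_ridge_blup,
    predict_linear,
    ridge_solve,
)
from gpbench.simulate import make_split_plan, simulate_genotypes, simulate_trait


class TestRidge:
    def test_constant_response_gives_zero_effects(self, toy_dataset):
        G, _, _ = toy_dataset
        y = np.full(G.n_lines, 0.7)
        fit = fit_ridge_blup(G, y)
        assert fit.intercept == pytest.approx(0.7)
        assert np.all(fit.marker_effects == 0)

    def test_closed_form_matches_numeric_optimizer(self, rng):
        n, p, lam = 50, 5, 2.0
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        b_closed = ridge_solve(X, y, lam)

        # independent oracle: brute-force minimization of the penalized
        # least-squares objective
        def objective(b):
            return np.sum((y - X @ b) ** 2) + lam * np.sum(b**2)

        res = optimize.minimize(objective, np.zeros(p), method="BFGS", tol=1e-14)
        assert np.allclose(b_closed, res.x, atol=1e-8)

    def test_dual_form_agrees_with_primal(self, rng):
        X = rng.normal(size=(10, 30))  # p > n triggers the dual path
        y = rng.normal(size=10)
        b_dual = ridge_solve(X, y, 3.0)
        A = X.T @ X + 3.0 * np.eye(30)
        b_primal = np.linalg.solve(A, X.T @ y)
        assert np.allclose(b_dual, b_primal, atol=1e-10)

    def test_fixed_lambda_fit_matches_oracle_with_intercept(self, rng):
        n, p, lam = 40, 6, 1.5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n) + 0.3

        def objective(theta):
            mu, b = theta[0], theta[1:]
            return np.sum((y - mu - X @ b) ** 2) + lam * np.sum(b**2)

        res = optimize.minimize(objective, np.zeros(p + 1), method="BFGS", tol=1e-14)
        fit = fit_ridge_blup(X, y, lambda_=lam)
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-6)
        assert np.allclose(fit.marker_effects, res.x[1:], atol=1e-6)

    def test_monotone_shrinkage_in_lambda(self, medium_dataset):
        G, pheno, _ = medium_dataset
        y = pheno.values[:, 0]
        norms = [
            np.linalg.norm(fit_ridge_blup(G, y, lambda_=lam).marker_effects)
            for lam in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_reml_ridge_predicts_high_heritability_trait(self):
        rs = []
        for seed in range(20):
            G = simulate_genotypes(500, 50, seed=1000 + seed)
            pheno, _ = simulate_trait(G, n_qtl=10, h2=0.9, seed=2000 + seed)
            y = pheno.values[:, 0]
            plan = make_split_plan(500, n_replicates=1, seed=seed)
            sp = plan.replicates[0]
            fit = fit_ridge_blup(G.X()[sp.train], y[sp.train])
            pred = predict_linear(fit, G.X()[sp.test])
            rs.append(np.corrcoef(pred, y[sp.test])[0, 1])
        assert np.median(rs) > 0.85

    def test_deterministic(self, toy_dataset):
        G, pheno, _ = toy_dataset
        y = pheno.values[:, 0]
        f1, f2 = fit_ridge_blup(G, y), fit_ridge_blup(G, y)
        assert np.array_equal(f1.marker_effects, f2.marker_effects)
        assert f1.lambda_ == f2.lambda_


class TestBayesianSamplers:
    def test_zero_signal_effects_near_zero(self, rng):
        n, p = 200, 50
        X = rng.integers(-1, 2, size=(n, p)).astype(float)
        y = rng.normal(size=n)
        fit = fit_bayesian_regression(
            X, y, model="BRR", iterations=3000, burn_in=500, seed=1
        )
        # posterior means should sit within 3 posterior sds of zero
        assert (np.abs(fit.marker_effects) < 3 * np.maximum(fit.effect_sd, 1e-6)).all()

    def test_brr_with_frozen_variances_matches_ridge_closed_form(self, rng):
        # conjugate-normal equivalence: with (s2e, s2b) fixed, the posterior
        # mean equals ridge with lambda = s2e/s2b.  Columns are centered so
        # the intercept decouples.
        n, p = 80, 15
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        beta = rng.normal(size=p) * 0.3
        y = X @ beta + rng.normal(size=n) * 0.5
        s2e, s2b = 0.25, 0.09
        fit = fit_bayesian_regression(
            X, y, model="BRR", iterations=12_000, burn_in=2_000, seed=2,
            fixed_variances=(s2e, s2b),
        )
        b_ridge = ridge_solve(X, y - y.mean(), s2e / s2b)
        mc_tol = 4 * fit.effect_sd.max() / np.sqrt((12_000 - 2_000) / 20)
        assert np.allclose(fit.marker_effects, b_ridge, atol=max(mc_tol, 0.01))

    def test_bayesb_without_point_mass_reduces_to_bayesa(self, rng):
        n, p = 150, 40
        X = rng.integers(-1, 2, size=(n, p)).astype(float)
        beta = np.zeros(p)
        beta[:5] = rng.normal(size=5)
        y = X @ beta + rng.normal(size=n)
        common = dict(iterations=12_000, burn_in=2_000, seed=3)
        fit_a = fit_bayesian_regression(X, y, model="BA", **common)
        fit_b = fit_bayesian_regression(
            X, y, model="BB", prior=BayesPrior(pi_zero=0.0), **common
        )
        sd = np.maximum(fit_a.effect_sd, fit_b.effect_sd)
        mc_tol = 6 * sd.max() / np.sqrt((12_000 - 2_000) / 20)
        assert np.allclose(
            fit_a.marker_effects, fit_b.marker_effects, atol=max(mc_tol, 0.02)
        )
        assert np.corrcoef(fit_a.marker_effects, fit_b.marker_effects)[0, 1] > 0.98

    def test_bayesa_approaches_brr_for_large_df(self, rng):
        # huge df pins every per-marker variance at the prior mode, which is
        # exactly the BRR structure with the same pinned variance
        n, p = 100, 20
        X = rng.integers(-1, 2, size=(n, p)).astype(float)
        y = X @ (rng.normal(size=p) * 0.2) + rng.normal(size=n) * 0.7
        common = dict(iterations=6000, burn_in=1000, seed=4)
        fit_a = fit_bayesian_regression(
            X, y, model="BA", prior=BayesPrior(df=5e4), **common
        )
        fit_r = fit_bayesian_regression(
            X, y, model="BRR", prior=BayesPrior(df=5e4), **common
        )
        assert np.corrcoef(fit_a.marker_effects, fit_r.marker_effects)[0, 1] > 0.99

    @pytest.mark.parametrize("model", ["BRR", "BA", "BB", "BL"])
    def test_seed_determinism(self, model, toy_dataset):
        G, pheno, _ = toy_dataset
        y = pheno.values[:, 0]
        kw = dict(iterations=400, burn_in=100, seed=7)
        f1 = fit_bayesian_regression(G, y, model=model, **kw)
        f2 = fit_bayesian_regression(G, y, model=model, **kw)
        assert np.array_equal(f1.marker_effects, f2.marker_effects)
        assert f1.sigma2_e == f2.sigma2_e

    @pytest.mark.parametrize("model", ["BA", "BL"])
    def test_samplers_recover_signal(self, model, medium_dataset):
        G, pheno, truth = medium_dataset
        y = pheno.values[:, 0]
        fit = fit_bayesian_regression(
            G, y, model=model, iterations=2000, burn_in=500, seed=8
        )
        beta_true = truth.full_effect_vector(G.n_markers)
        assert np.corrcoef(fit.marker_effects, beta_true)[0, 1] > 0.5

    def test_constant_response_rejected(self, toy_dataset):
        G, _, _ = toy_dataset
        with pytest.raises(DegenerateTraitError):
            fit_bayesian_regression(G, np.ones(G.n_lines), model="BRR")

    def test_iterations_must_exceed_burn_in(self, toy_dataset):
        G, pheno, _ = toy_dataset
        with pytest.raises(ValueError):
            fit_bayesian_regression(
                G, pheno.values[:, 0], model="BRR", iterations=100, burn_in=100
            )


class TestPredictLinear:
    def test_zero_effects_constant_prediction(self, toy_dataset):
        G, _, _ = toy_dataset
        fit = fit_ridge_blup(G, np.full(G.n_lines, 0.3))
        assert np.allclose(predict_linear(fit, G), 0.3)

    def test_single_marker_identity(self, rng):
        from gpbench.linear import LinearModelFit

        X = rng.integers(-1, 2, size=(10, 1)).astype(float)
        fit = LinearModelFit(
            algorithm="rrBLUP", intercept=0.0, marker_effects=np.array([1.0]),
            sigma2_e=0.0,
        )
        assert np.array_equal(predict_linear(fit, X), X[:, 0])

    def test_in_sample_predictions_match_fit_record(self, toy_dataset):
        G, pheno, _ = toy_dataset
        y = pheno.values[:, 0]
        fit = fit_ridge_blup(G, y)
        assert np.array_equal(predict_linear(fit, G), fit.fitted_values)
        fit_b = fit_bayesian_regression(
            G, y, model="BL", iterations=500, burn_in=100, seed=9
        )
        assert np.array_equal(predict_linear(fit_b, G), fit_b.fitted_values)

    def test_marker_mismatch_raises(self, toy_dataset, rng):
        G, pheno, _ = toy_dataset
        fit = fit_ridge_blup(G, pheno.values[:, 0])
        with pytest.raises(AlignmentError):
            predict_linear(fit, rng.normal(size=(5, G.n_markers + 1)))
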