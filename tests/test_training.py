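"""Hybrid ANFIS learning: LSE consequents, premise gradients, training loop."""

import numpy as np
import pytest

from myoanfis import (
    ClusterConfig,
    GaussianMF,
    FuzzyRule,
    SugenoFIS,
    TrainConfig,
    build_initial_fis,
    cluster,
    design_matrix,
    hybrid_fit,
    lse_consequents,
    premise_gradients,
)

from conftest import make_random_fis


def brute_design_matrix(fis, X):
    """Elementwise loop construction of the consequent regressor matrix."""
    X = np.atleast_2d(X)
    rows = []
    for x in X:
        w = np.array(
            [
                np.prod([np.exp(-((x[j] - mf.center) ** 2) / (2 * mf.sigma**2))
                         for j, mf in enumerate(rule.premises)])
                for rule in fis.rules
            ]
        )
        wbar = w / w.sum()
        row = []
        for i in range(len(fis.rules)):
            if fis.order == "first":
                row.extend(wbar[i] * x)
            row.append(wbar[i])
        rows.append(row)
    return np.array(rows)


class TestDesignMatrix:
    def test_single_rule_zero_order_is_ones(self, rng):
        fis = make_random_fis(rng, 2, 1, order="zero")
        A = design_matrix(fis, rng.normal(size=(5, 2)))
        np.testing.assert_allclose(A, np.ones((5, 1)))

    def test_single_rule_first_order_row(self, rng):
        fis = make_random_fis(rng, 3, 1, order="first")
        x = rng.normal(size=3)
        A = design_matrix(fis, x[None, :])
        np.testing.assert_allclose(A[0], np.append(x, 1.0))

    @pytest.mark.parametrize("order", ["zero", "first"])
    def test_matches_brute_force(self, rng, order):
        fis = make_random_fis(rng, 3, 2, order=order)
        X = rng.normal(size=(3, 3))
        np.testing.assert_allclose(design_matrix(fis, X), brute_design_matrix(fis, X), rtol=1e-12)


class TestLSE:
    def test_single_rule_zero_order_fits_mean(self, rng):
        fis = make_random_fis(rng, 2, 1, order="zero")
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        fit = lse_consequents(fis, X, y)
        assert fit.rules[0].consequent[0] == pytest.approx(y.mean())

    def test_recovers_generating_consequents(self, rng):
        truth = make_random_fis(rng, 3, 3, order="first")
        X = rng.normal(size=(100, 3))
        y = truth.evaluate_batch(X)
        blank = make_random_fis(rng, 3, 3, order="first")
        blank.set_premises(truth.centers, truth.sigmas)
        fit = lse_consequents(blank, X, y)
        np.testing.assert_allclose(
            fit.consequent_matrix(), truth.consequent_matrix(), rtol=1e-8
        )

    def test_zero_targets_give_zero_consequents(self, rng):
        fis = make_random_fis(rng, 2, 5, order="first")
        X = rng.normal(size=(4, 2))  # underdetermined -> minimum norm
        fit = lse_consequents(fis, X, np.zeros(4))
        np.testing.assert_allclose(fit.consequent_matrix(), 0.0, atol=1e-12)

    def test_residual_orthogonal_to_design_columns(self, rng):
        fis = make_random_fis(rng, 2, 3, order="first")
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        fit = lse_consequents(fis, X, y)
        A = design_matrix(fis, X)
        resid = fit.evaluate_batch(X) - y
        np.testing.assert_allclose(A.T @ resid, 0.0, atol=1e-8)

    def test_lse_is_global_optimum_over_consequents(self, rng):
        fis = make_random_fis(rng, 2, 2, order="first")
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        fit = lse_consequents(fis, X, y)
        sse0 = np.sum((fit.evaluate_batch(X) - y) ** 2)
        for _ in range(10):
            perturbed = lse_consequents(fis, X, y)
            for rule in perturbed.rules:
                rule.consequent = rule.consequent + rng.normal(scale=1e-3, size=rule.consequent.shape)
            sse = np.sum((perturbed.evaluate_batch(X) - y) ** 2)
            assert sse >= sse0 - 1e-12


class TestPremiseGradients:
    def test_zero_at_perfect_fit(self, rng):
        fis = make_random_fis(rng, 2, 3, order="first")
        X = rng.normal(size=(30, 2))
        y = fis.evaluate_batch(X)  # residuals exactly zero
        dC, dS = premise_gradients(fis, X, y)
        np.testing.assert_allclose(dC, 0.0, atol=1e-10)
        np.testing.assert_allclose(dS, 0.0, atol=1e-10)

    def test_single_rule_premises_have_no_effect(self, rng):
        fis = make_random_fis(rng, 3, 1, order="first")
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        dC, dS = premise_gradients(fis, X, y)
        np.testing.assert_allclose(dC, 0.0, atol=1e-12)
        np.testing.assert_allclose(dS, 0.0, atol=1e-12)

    @pytest.mark.parametrize("order", ["zero", "first"])
    def test_matches_central_finite_differences(self, rng, order):
        # 50 random instances across both consequent orders
        for _ in range(25):
            n_in = int(rng.integers(1, 4))
            L = int(rng.integers(2, 5))
            fis = make_random_fis(rng, n_in, L, order=order)
            X = rng.normal(size=(10, n_in))
            y = rng.normal(size=10)
            dC, dS = premise_gradients(fis, X, y)

            def sse(f):
                return float(np.sum((f.evaluate_batch(X) - y) ** 2))

            h = 1e-6
            for i in (0, L - 1):
                for j in range(n_in):
                    for attr, grad in (("center", dC), ("sigma", dS)):
                        orig = getattr(fis.rules[i].premises[j], attr)
                        setattr(fis.rules[i].premises[j], attr, orig + h)
                        up = sse(fis)
                        setattr(fis.rules[i].premises[j], attr, orig - h)
                        down = sse(fis)
                        setattr(fis.rules[i].premises[j], attr, orig)
                        fd = (up - down) / (2 * h)
                        assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestHybridFit:
    def test_exact_data_converges_immediately(self, rng):
        truth = make_random_fis(rng, 2, 2, order="first")
        X = rng.normal(size=(60, 2))
        y = truth.evaluate_batch(X)
        init = make_random_fis(rng, 2, 2, order="first")
        init.set_premises(truth.centers, truth.sigmas)
        report = hybrid_fit(init, X, y, TrainConfig(epochs=50))
        assert report.errors[0] < 1e-8
        assert report.converged
        assert len(report.errors) == 1

    def test_monotone_improvement_on_two_cluster_regression(self, rng):
        X = np.concatenate([rng.normal(0.25, 0.05, 100), rng.normal(0.75, 0.05, 100)])[:, None]
        y = np.where(X.ravel() < 0.5, 0.1, 0.9) + rng.normal(0, 0.02, 200)
        init = SugenoFIS(
            rules=[
                FuzzyRule([GaussianMF(0.35, 0.3)], np.zeros(1)),
                FuzzyRule([GaussianMF(0.65, 0.3)], np.zeros(1)),
            ],
            order="zero",
        )
        report = hybrid_fit(init, X, y, TrainConfig(epochs=50, learning_rate=0.005))
        assert report.errors[-1] < report.errors[0]
        assert np.all(np.diff(report.errors) <= 1e-15)  # error after LSE never increases

    def test_error_sequence_finite_and_bounded_by_epochs(self, rng):
        fis = make_random_fis(rng, 2, 2)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        report = hybrid_fit(fis, X, y, TrainConfig(epochs=10))
        assert len(report.errors) <= 10
        assert np.all(np.isfinite(report.errors))

    def test_deterministic_under_fixed_config(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        init = make_random_fis(np.random.default_rng(7), 2, 3)
        r1 = hybrid_fit(init, X, y, TrainConfig(epochs=15))
        r2 = hybrid_fit(init, X, y, TrainConfig(epochs=15))
        assert r1.errors == r2.errors
        np.testing.assert_array_equal(r1.fis.centers, r2.fis.centers)
        np.testing.assert_array_equal(r1.fis.consequent_matrix(), r2.fis.consequent_matrix())

    def test_sigma_stays_positive(self, rng):
        fis = make_random_fis(rng, 1, 3)
        X = rng.normal(size=(30, 1))
        y = rng.normal(size=30) * 100
        report = hybrid_fit(fis, X, y, TrainConfig(epochs=30, learning_rate=1.0))
        assert np.all(report.fis.sigmas > 0)

    def test_clustering_seeded_recovery(self, rng):
        # rule centers of a known 2-rule model sit at the data cluster centers;
        # the subtractive-clustering seed + hybrid training relocates them to
        # within 0.05 normalized units despite observation noise
        X = np.concatenate([rng.normal(0.25, 0.05, 250), rng.normal(0.75, 0.05, 250)]).clip(0, 1)[:, None]
        truth = SugenoFIS(
            rules=[
                FuzzyRule([GaussianMF(0.25, 0.15)], np.array([0.2])),
                FuzzyRule([GaussianMF(0.75, 0.15)], np.array([0.8])),
            ],
            order="zero",
        )
        y = truth.evaluate_batch(X) + rng.normal(0, 0.01, len(X))
        res = cluster(X, ClusterConfig(ra=0.5))
        fis0 = build_initial_fis(res, order="zero", data=X)
        report = hybrid_fit(fis0, X, y, TrainConfig(epochs=100, learning_rate=0.005, tolerance=1e-9))
        centers = np.sort(report.fis.centers.ravel())
        np.testing.assert_allclose(centers, [0.25, 0.75], atol=0.05)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
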