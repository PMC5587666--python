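"""Prediction, metrics, cross-validation hygiene and posterior summaries."""

import numpy as np
import pytest

import dpreg
from dpreg.errors import DegeneratePredictionWarning, InvalidParameterError
from dpreg.evaluate import (
    FitSummary,
    compute_grm,
    effective_segments,
    monte_carlo_cv,
    mse,
    pip_from_draws,
    predict,
    pve_from_draws,
    r_squared,
    ridge_backend,
    standardize_genotypes,
)


class TestPredict:
    def test_intercept_only(self):
        fit = FitSummary(alpha_mean=np.array([2.0]), beta_mean=np.zeros(3))
        yhat = predict(fit, np.ones((4, 1)), np.zeros((4, 3)))
        np.testing.assert_allclose(yhat, 2.0)

    def test_hand_arithmetic(self):
        fit = FitSummary(alpha_mean=np.array([1.0, 0.5]),
                         beta_mean=np.array([2.0]))
        W = np.array([[1.0, 2.0], [1.0, 0.0], [1.0, -2.0]])
        X = np.array([[1.0], [0.0], [-1.0]])
        np.testing.assert_allclose(predict(fit, W, X), [4.0, 1.0, -2.0])

    def test_true_coefficients_give_perfect_r2(self):
        gm = dpreg.simulate_genotypes(80, 30, seed=1)
        ds = dpreg.simulate_phenotype(
            gm, dpreg.SimulationSpec(scenario="IV", pve=0.9, seed=2))
        Xc, _ = dpreg.center_genotypes(gm)
        fit = FitSummary(alpha_mean=np.array([0.0]), beta_mean=ds.beta_true)
        yhat = predict(fit, np.ones((80, 1)), Xc)
        g = gm.dosages @ ds.beta_true
        assert r_squared(g, yhat) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        fit = FitSummary(alpha_mean=np.zeros(1), beta_mean=np.zeros(2))
        with pytest.raises(InvalidParameterError):
            predict(fit, np.ones((3, 1)), np.zeros((3, 5)))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert mse(y, y) == 0.0

    def test_sign_flip_keeps_r2(self):
        y = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, -y) == pytest.approx(1.0)
        assert mse(y, -y) == pytest.approx(4 * np.mean(y**2))

    def test_hand_computed_example(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.0, 1.0, 2.0])
        assert r_squared(y, yhat) == pytest.approx(0.75)
        assert mse(y, yhat) == pytest.approx(2.0 / 3.0)

    def test_degenerate_prediction_flagged(self):
        with pytest.warns(DegeneratePredictionWarning):
            assert r_squared(np.array([1.0, 2.0, 3.0]), np.ones(3)) == 0.0

    def test_r2_affine_invariance_mse_not(self):
        rng = np.random.default_rng(3)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        r2 = r_squared(y, yhat)
        for a, b in [(2.0, 1.0), (0.3, -4.0)]:
            assert r_squared(y, a * yhat + b) == pytest.approx(r2, abs=1e-12)
            assert mse(y, a * yhat + b) != pytest.approx(mse(y, yhat))


class TestMonteCarloCV:
    def _data(self, n=60, p=20, seed=4):
        gm = dpreg.simulate_genotypes(n, p, seed=seed)
        ds = dpreg.simulate_phenotype(
            gm, dpreg.SimulationSpec(scenario="IV", pve=0.5, seed=seed + 1))
        return ds.phenotype, np.ones((n, 1)), gm.dosages

    def test_split_count_disjointness_determinism(self):
        y, W, X = self._data()
        rep1 = monte_carlo_cv(y, W, X, ridge_backend(), n_splits=6, seed=5)
        rep2 = monte_carlo_cv(y, W, X, ridge_backend(), n_splits=6, seed=5)
        assert len(rep1.splits) == 6 and rep1.r2.shape == (6,)
        np.testing.assert_array_equal(rep1.r2, rep2.r2)
        for tr, te in rep1.splits:
            assert set(tr) & set(te) == set()
            assert len(tr) + len(te) == len(y)

    def test_no_leakage_from_test_fold(self):
        """Corrupting the held-out fold's raw values leaves the training-fold
        preprocessing and fit untouched."""
        y, W, X = self._data()
        captured = {}

        def spy(y_tr, W_tr, Xc_tr):
            captured.setdefault("snapshots", []).append(
                (y_tr.copy(), Xc_tr.copy()))
            return ridge_backend()(y_tr, W_tr, Xc_tr)

        rep = monte_carlo_cv(y, W, X, spy, n_splits=1, seed=6,
                             normalize_phenotype=True)
        first = captured["snapshots"][0]
        te = rep.splits[0][1]
        y2, X2 = y.copy(), X.copy()
        y2[te] = np.random.default_rng(0).permutation(y2[te])
        X2[te] += 1.0
        captured.clear()
        monte_carlo_cv(y2, W, X2, spy, n_splits=1, seed=6,
                       normalize_phenotype=True)
        second = captured["snapshots"][0]
        np.testing.assert_array_equal(first[0], second[0])
        np.testing.assert_array_equal(first[1], second[1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            monte_carlo_cv(np.zeros(5), np.ones((5, 1)), np.zeros((5, 2)),
                           ridge_backend())


class TestPosteriorSummaries:
    def test_pve_trivial_limits(self):
        assert pve_from_draws(np.zeros(10))["mean"] == 0.0
        out = pve_from_draws(np.full(10, 0.73))
        assert out["mean"] == pytest.approx(0.73)
        assert out["ci95"] == (pytest.approx(0.73), pytest.approx(0.73))

    def test_pip_trivial_cases(self):
        sigma2k = np.tile([1.0, 0.01], (5, 1))  # component 1 is the background
        always_bg = np.ones((5, 3), dtype=int)
        np.testing.assert_allclose(
            pip_from_draws(always_bg, sigma2k), [0.0, 0.0, 0.0])
        never_bg = np.zeros((5, 3), dtype=int)
        np.testing.assert_allclose(
            pip_from_draws(never_bg, sigma2k), [1.0, 1.0, 1.0])

    def test_pip_k1_warns(self):
        with pytest.warns(UserWarning, match="K=1"):
            out = pip_from_draws(np.zeros((4, 3), dtype=int), np.ones((4, 1)))
        np.testing.assert_allclose(out, 0.0)

    def test_planted_large_effect_snp_has_high_pip(self):
        """A sparse large-effect group should stand out from the background."""
        gm = dpreg.simulate_genotypes(400, 200, seed=7)
        ds = dpreg.simulate_phenotype(
            gm, dpreg.SimulationSpec(scenario="III", c_large=10, pve=0.8, seed=8))
        Xc, _ = dpreg.center_genotypes(gm)
        data = dpreg.RegressionData(y=ds.phenotype, W=np.ones((400, 1)), X=Xc)
        draws = dpreg.run_gibbs(data, dpreg.DPRPrior(K=4),
                                dpreg.MCMCConfig(n_iter=1200, burn_in=300,
                                                 thin=3, seed=9))
        planted = ds.group_labels == 1
        assert draws.pip[planted].mean() > np.median(draws.pip[~planted])


class TestRelatedness:
    def test_grm_symmetry_trace_and_duplicates(self):
        rng = np.random.default_rng(10)
        X = rng.binomial(2, 0.3, size=(20, 300)).astype(float)
        X[1] = X[0]  # duplicated individual
        Xs = standardize_genotypes(X)
        grm = compute_grm(Xs)
        np.testing.assert_allclose(grm, grm.T)
        assert np.trace(grm) == pytest.approx(20, rel=1e-6)
        assert grm[0, 1] == pytest.approx(grm[0, 0], rel=1e-6)

    def test_unrelated_offdiagonals_small_and_me_near_p(self):
        rng = np.random.default_rng(11)
        p = 500
        X = rng.binomial(2, 0.4, size=(40, p)).astype(float)
        grm = compute_grm(standardize_genotypes(X))
        off = grm[~np.eye(40, dtype=bool)]
        assert np.var(off) == pytest.approx(1.0 / p, rel=0.3)
        assert effective_segments(grm) == pytest.approx(p, rel=0.3)

    def test_too_few_snps_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_grm(np.zeros((5, 1)))
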