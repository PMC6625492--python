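"""GP regression, Thompson sampling, LOO q², relevance, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import solvoptim as sv
from solvoptim.errors import (
    InvalidArgumentError,
    UndefinedQuantityError,
    UnsupportedConfigError,
)
from solvoptim.surrogate import kernel_matrix


def closed_form_posterior(X, y, Xs, ls, sf2, noise, kernel="matern52"):
    """Independent dense-linear-algebra GP posterior (textbook equations)."""
    ls = np.asarray(ls, dtype=float)

    def k(A, B):
        d2 = (((A[:, None, :] - B[None, :, :]) / ls) ** 2).sum(-1)
        if kernel == "matern52":
            r = np.sqrt(d2)
            s5 = np.sqrt(5.0)
            return sf2 * (1 + s5 * r + 5 * d2 / 3) * np.exp(-s5 * r)
        return sf2 * np.exp(-0.5 * d2)

    K = k(X, X) + noise * np.eye(len(X))
    Ks = k(Xs, X)
    Kinv = np.linalg.inv(K)
    mean = Ks @ Kinv @ y
    var = np.diag(k(Xs, Xs) - Ks @ Kinv @ Ks.T)
    return mean, var


class TestFitPredict:
    def test_noise_free_interpolation(self, rng):
        X = np.linspace(-2, 2, 8)[:, None]
        y = np.sin(X[:, 0])
        gp = sv.fit_gp(X, y, sv.GPConfig(), seed=0)
        mean, _ = predict_at(gp, X)
        np.testing.assert_allclose(mean, y, atol=1e-4)

    @pytest.mark.parametrize("kernel", ["matern52", "rbf"])
    def test_matches_closed_form_oracle(self, fitted_toy_gp, kernel, rng):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.3, -1.0]])
        y = np.array([1.0, -0.5, 0.7])
        ls = np.array([0.8, 1.3])
        cfg = sv.GPConfig(kernel=kernel, optimize=False, normalize=False,
                          lengthscales=ls, signal_variance=1.2,
                          noise_variance=0.05)
        gp = sv.fit_gp(X, y, cfg, seed=0)
        Xs = rng.uniform(-2, 2, size=(7, 2))
        mean, var = sv.predict(gp, Xs, include_noise=False)
        mo, vo = closed_form_posterior(X, y, Xs, ls, 1.2, 0.05, kernel)
        np.testing.assert_allclose(mean, mo, atol=1e-10)
        np.testing.assert_allclose(var, vo, atol=1e-10)

    def test_prior_reversion_far_away(self, fitted_toy_gp):
        gp, X, y = fitted_toy_gp
        far = np.array([[60.0, -55.0]])
        mean, var = sv.predict(gp, far, include_noise=True)
        assert abs(mean[0]) < 1e-2 * max(1.0, np.abs(y).max())
        np.testing.assert_allclose(
            var[0], gp.signal_variance + gp.noise_variance, rtol=0.01)

    def test_variance_floor_and_dim_check(self, fitted_toy_gp, rng):
        gp, X, y = fitted_toy_gp
        Xs = rng.uniform(-1, 1, size=(20, 2))
        _, var = sv.predict(gp, Xs, include_noise=True)
        assert np.all(var >= gp.noise_variance - 1e-12)
        with pytest.raises(InvalidArgumentError):
            sv.predict(gp, np.zeros((2, 3)))

    def test_refit_bit_reproducible(self, rng):
        X = rng.uniform(-1, 1, size=(10, 2))
        y = np.tanh(X[:, 0] * 2) + 0.1 * X[:, 1]
        a = sv.fit_gp(X, y, sv.GPConfig(n_restarts=4), seed=9)
        b = sv.fit_gp(X, y, sv.GPConfig(n_restarts=4), seed=9)
        np.testing.assert_array_equal(a.lengthscales, b.lengthscales)
        assert a.signal_variance == b.signal_variance
        assert a.noise_variance == b.noise_variance

    def test_input_validation(self):
        with pytest.raises(InvalidArgumentError):
            sv.fit_gp(np.zeros((1, 2)), np.zeros(1))
        with pytest.raises(InvalidArgumentError):
            sv.fit_gp(np.zeros((3, 2)), np.zeros(2))

    def test_monotone_information(self, rng):
        """A new noise-free observation never increases posterior variance."""
        cfg = sv.GPConfig(optimize=False, normalize=False,
                          lengthscales=np.array([1.0]), signal_variance=1.0,
                          noise_variance=1e-8)
        X = rng.uniform(-3, 3, size=(6, 1))
        y = np.sin(X[:, 0])
        gp = sv.fit_gp(X, y, cfg, seed=0)
        probes = np.linspace(-3, 3, 25)[:, None]
        _, v_before = sv.predict(gp, probes, include_noise=False)
        gp2 = gp.condition(np.array([[0.7]]), [np.sin(0.7)])
        _, v_after = sv.predict(gp2, probes, include_noise=False)
        assert np.all(v_after <= v_before + 1e-8)


def predict_at(gp, X):
    return sv.predict(gp, X, include_noise=False)


class TestThompsonSampling:
    def test_seeded_determinism(self, fitted_toy_gp, rng):
        gp, _, _ = fitted_toy_gp
        probes = rng.uniform(-1, 1, size=(10, 2))
        f1 = sv.sample_posterior_function(gp, 256, seed=42)
        f2 = sv.sample_posterior_function(gp, 256, seed=42)
        np.testing.assert_array_equal(f1(probes), f2(probes))
        f3 = sv.sample_posterior_function(gp, 256, seed=43)
        assert not np.array_equal(f1(probes), f3(probes))

    def test_ensemble_moments_match_posterior(self, fitted_toy_gp, rng):
        gp, _, _ = fitted_toy_gp
        probes = rng.uniform(-1.5, 1.5, size=(4, 2))
        n_draws = 2000
        draws = np.array([
            sv.sample_posterior_function(gp, 512, seed=s)(probes)
            for s in range(n_draws)
        ])
        mean, var = sv.predict(gp, probes, include_noise=False)
        se = draws.std(axis=0, ddof=1) / np.sqrt(n_draws)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * se)
        # variance agreement at the same confidence scale
        var_se = draws.var(axis=0, ddof=1) * np.sqrt(2.0 / (n_draws - 1))
        assert np.all(np.abs(draws.var(axis=0, ddof=1) - var) < 4 * var_se)

    def test_spectral_resolution_improves_variance_match(self, fitted_toy_gp):
        gp, _, _ = fitted_toy_gp
        probes = np.array([[0.5, 0.2], [-0.4, 0.9]])
        _, var = sv.predict(gp, probes, include_noise=False)

        def discrepancy(M, n_draws=400):
            draws = np.array([
                sv.sample_posterior_function(gp, M, seed=1000 + s)(probes)
                for s in range(n_draws)
            ])
            return np.abs(draws.var(axis=0) - var).max()

        # average over repeated small ensembles to damp Monte-Carlo noise
        assert discrepancy(1000) <= discrepancy(25) + 0.05

    def test_unsupported_kernel_rejected(self, fitted_toy_gp):
        gp, _, _ = fitted_toy_gp
        gp2 = sv.GPSurrogate(**{**gp.__dict__, "kernel": "matern52"})
        gp2.kernel = "weird"
        with pytest.raises(UnsupportedConfigError):
            sv.sample_posterior_function(gp2, 16, seed=0)


class TestLoocv:
    def test_perfect_and_null_predictions(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        assert sv.q2_score(y, y) == 1.0
        np.testing.assert_allclose(sv.q2_score(y, np.full(4, y.mean())), 0.0,
                                   atol=1e-12)

    def test_matches_naive_refit_loop(self, rng):
        X = rng.uniform(-2, 2, size=(12, 2))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1] + rng.normal(0, 0.05, 12)
        cfg = sv.GPConfig(n_restarts=3)
        q2, preds = sv.loocv_q2(X, y, cfg, seed=5)
        # independent naive loop: refit from scratch per fold, same seeds
        child = np.random.SeedSequence(5).generate_state(12)
        oracle_preds = np.empty(12)
        for i in range(12):
            mask = np.ones(12, dtype=bool)
            mask[i] = False
            m = sv.fit_gp(X[mask], y[mask], cfg, seed=int(child[i] % (2**31)))
            oracle_preds[i] = sv.predict(m, X[i:i + 1])[0][0]
        press = np.sum((y - oracle_preds) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        np.testing.assert_allclose(q2, 1 - press / tss, atol=1e-6)
        np.testing.assert_allclose(preds, oracle_preds, atol=1e-6)

    def test_affine_invariance(self, rng):
        X = rng.uniform(-2, 2, size=(10, 1))
        y = np.cos(X[:, 0])
        q2a, preds = sv.loocv_q2(X, y, sv.GPConfig(n_restarts=2), seed=1)
        # matched affine rescaling of y and predictions leaves q² unchanged
        q2b = sv.q2_score(3.0 * y - 7.0, 3.0 * preds - 7.0)
        np.testing.assert_allclose(q2a, q2b, atol=1e-10)

    def test_pearson_variant_and_errors(self, rng):
        X = rng.uniform(-2, 2, size=(8, 1))
        y = X[:, 0] ** 2
        q2p, _ = sv.loocv_q2(X, y, sv.GPConfig(n_restarts=2), seed=2,
                             formula="pearson")
        assert 0.0 <= q2p <= 1.0
        with pytest.raises(UndefinedQuantityError):
            sv.loocv_q2(X, np.ones(8), sv.GPConfig(), seed=0)
        with pytest.raises(InvalidArgumentError):
            sv.loocv_q2(X[:2], y[:2], sv.GPConfig(), seed=0)


class TestRelevance:
    def test_reported_length_scales_rank_neutral_segment_first(self):
        """The σ-segment ranking implied by published ARD length scales."""
        ls = np.array([4.41, 6.86, 1.07, 10.21, 2.92])
        gp = _dummy_gp(ls)
        names = [f"sigma_{i}" for i in range(1, 6)]
        ranking = sv.relevance_ranking(gp, names)
        assert ranking[0][0] == "sigma_3"
        assert [n for n, _ in ranking] == [
            "sigma_3", "sigma_5", "sigma_1", "sigma_2", "sigma_4"]

    def test_tie_break_by_input_order(self):
        gp = _dummy_gp(np.array([2.0, 2.0, 2.0]))
        ranking = sv.relevance_ranking(gp, ["a", "b", "c"])
        assert [n for n, _ in ranking] == ["a", "b", "c"]

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_matches_sort_oracle(self, scales):
        ls = np.array(scales)
        gp = _dummy_gp(ls)
        names = [f"f{i}" for i in range(len(ls))]
        ranking = sv.relevance_ranking(gp, names)
        assert [v for _, v in ranking] == sorted(ls.tolist())

    def test_non_ard_rejected(self, rng):
        X = rng.uniform(-1, 1, size=(6, 2))
        y = X.sum(axis=1)
        gp = sv.fit_gp(X, y, sv.GPConfig(ard=False, n_restarts=2), seed=0)
        with pytest.raises(UnsupportedConfigError):
            sv.relevance_ranking(gp, ["a", "b"])


def _dummy_gp(ls):
    X = np.zeros((2, len(ls)))
    X[1] = 1.0
    cfg = sv.GPConfig(optimize=False, normalize=False, lengthscales=ls,
                      signal_variance=1.0, noise_variance=0.1)
    return sv.fit_gp(X, np.array([0.0, 1.0]), cfg, seed=0)


class TestThresholdClassification:
    def test_stated_thresholds(self):
        conv_high, de_high, joint = sv.classify_by_threshold(90.0, 70.0, (80, 65))
        assert conv_high and de_high and joint

    def test_boundary_is_strict(self):
        conv_high, de_high, joint = sv.classify_by_threshold(80.0, 65.0, (80, 65))
        assert not conv_high and not de_high and not joint

    def test_joint_count_matches_row_scan(self, rng):
        conv = rng.uniform(0, 100, 200)
        de = rng.uniform(-100, 100, 200)
        _, _, joint = sv.classify_by_threshold(conv, de, (80, 65))
        oracle = sum(1 for c, d in zip(conv, de) if c > 80 and d > 65)
        assert joint.sum() == oracle


class TestParameterRecovery:
    def test_ard_recovers_relevance_ordering(self):
        """Data from a known ARD kernel: length-scale order is recovered."""
        true_ls = np.array([0.25, 1.0, 4.0])  # 4× separation
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            X = rng.uniform(-2, 2, size=(60, 3))
            K = kernel_matrix(X / 1.0, X / 1.0, "matern52", true_ls, 1.0)
            y = rng.multivariate_normal(np.zeros(60), K + 1e-6 * np.eye(60))
            gp = sv.fit_gp(X, y, sv.GPConfig(n_restarts=5, normalize=False),
                           seed=rep)
            if list(np.argsort(gp.lengthscales)) == [0, 1, 2]:
                hits += 1
        assert hits >= n_rep - 1
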