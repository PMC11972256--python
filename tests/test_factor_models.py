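import numpy as np
import pytest

import vizlit as vz
from vizlit.factor_models import (
    center,
    compare_factor_models,
    cv_latent_mse,
    estimate_factor_scores,
    fit_latent_fa,
    idealized_loading,
    idealized_mse,
    make_folds,
    mse_summary,
    predict_responses,
    select_n_factors,
    varimax,
)

from _oracles import normal_equation_scores


class TestCenter:
    def test_constant_row_centers_to_zero(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        Xc, mu = center(X)
        np.testing.assert_allclose(Xc[0], 0.0)
        np.testing.assert_allclose(mu, [1.0, 2.0])

    def test_two_entry_row(self):
        Xc, mu = center(np.array([[0.0, 1.0]]))
        np.testing.assert_allclose(Xc, [[-0.5, 0.5]])

    def test_row_means_vanish_on_random_binary(self):
        rng = np.random.default_rng(0)
        X = (rng.random((66, 100)) < 0.3).astype(float)
        Xc, _ = center(X)
        assert np.abs(Xc.mean(axis=1)).max() < 1e-12


class TestIdealizedLoading:
    def test_combined_shapes(self, bank):
        assert idealized_loading(bank, "question_type").shape == (66, 11)
        assert idealized_loading(bank, "graph_type").shape == (66, 13)
        L = idealized_loading(bank, "test")
        assert L.shape == (66, 2)
        np.testing.assert_array_equal(L.L.sum(axis=0), [13, 53])

    def test_every_row_sums_to_one(self, bank):
        for facet in ("test", "graph_type", "question_type"):
            L = idealized_loading(bank, facet)
            np.testing.assert_array_equal(L.L.sum(axis=1), 1.0)

    def test_unknown_facet(self, bank):
        with pytest.raises(ValueError, match="facet"):
            idealized_loading(bank, "color")


class TestFactorScores:
    def test_identity_loading_returns_data(self):
        rng = np.random.default_rng(1)
        Xc, _ = center(rng.random((6, 9)))
        F = estimate_factor_scores(np.eye(6), Xc)
        np.testing.assert_allclose(F.F, Xc, atol=1e-12)

    def test_single_all_ones_factor_is_column_mean(self):
        rng = np.random.default_rng(2)
        Xc, _ = center(rng.random((8, 5)))
        F = estimate_factor_scores(np.ones((8, 1)), Xc)
        np.testing.assert_allclose(F.F[0], Xc.mean(axis=0), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equation_oracle(self, seed):
        """OLS scores equal the brute-force normal-equation solution."""
        rng = np.random.default_rng(seed)
        m, f, n = 20, 8, 12
        assign = rng.integers(0, f, size=m)
        assign[:f] = np.arange(f)  # full column rank
        L = np.zeros((m, f))
        L[np.arange(m), assign] = 1.0
        Xc, _ = center(rng.random((m, n)))
        ours = estimate_factor_scores(L, Xc).F
        oracle = normal_equation_scores(L, Xc)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_disjoint_indicator_equals_category_means(self, bank):
        rng = np.random.default_rng(3)
        Xc, _ = center((rng.random((66, 30)) < 0.3).astype(float))
        L = idealized_loading(bank, "graph_type")
        F = estimate_factor_scores(L, Xc)
        for j, lab in enumerate(L.factor_labels):
            rows = L.L[:, j] == 1.0
            np.testing.assert_allclose(F.F[j], Xc[rows].mean(axis=0), atol=1e-10)

    def test_rank_deficient_rejected(self):
        L = np.ones((5, 2))
        with pytest.raises(ValueError, match="rank"):
            estimate_factor_scores(L, np.zeros((5, 3)))


class TestLatentFa:
    def test_generative_covariance_recovery(self):
        """A 2-factor fit reproduces the covariance of exact 2-factor data."""
        rng = np.random.default_rng(4)
        m, n, f = 20, 4000, 2
        L0 = rng.normal(size=(m, f))
        X = L0 @ rng.normal(size=(f, n)) + 0.05 * rng.normal(size=(m, n))
        Xc, _ = center(X)
        fit = fit_latent_fa(Xc, f)
        S = (Xc @ Xc.T) / n
        sigma = fit.L @ fit.L.T + np.diag(fit.uniquenesses)
        rel = np.linalg.norm(sigma - S) / np.linalg.norm(S)
        assert rel < 0.01

    def test_zero_factor_baseline_predicts_mu(self):
        rng = np.random.default_rng(5)
        X = (rng.random((10, 40)) < 0.4).astype(float)
        Xc, mu = center(X)
        fit = fit_latent_fa(Xc, 0)
        assert fit.L.shape == (10, 0)
        F = estimate_factor_scores(fit.L, Xc)
        pred = predict_responses(fit.L, F, mu)
        np.testing.assert_allclose(pred, mu[:, None] * np.ones((1, 40)))

    def test_loglik_rotation_invariant(self):
        rng = np.random.default_rng(6)
        Xc, _ = center(rng.random((12, 200)))
        fit = fit_latent_fa(Xc, 3)
        # random orthogonal rotation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        from vizlit.factor_models import _gaussian_fa_loglik

        S = (Xc @ Xc.T) / 200
        ll_rot = _gaussian_fa_loglik(S, fit.L @ Q, fit.uniquenesses, 200)
        assert ll_rot == pytest.approx(fit.loglik, abs=1e-8)

    def test_heywood_floor_warns(self):
        rng = np.random.default_rng(7)
        # two near-duplicate factor indicators force their uniquenesses to ~0
        f0 = rng.normal(size=400)
        X = np.vstack([f0 + 1e-3 * rng.normal(size=400),
                       f0 + 1e-3 * rng.normal(size=400),
                       rng.normal(size=400),
                       rng.normal(size=400)])
        Xc, _ = center(X)
        with pytest.warns(RuntimeWarning, match="Heywood"):
            fit = fit_latent_fa(Xc, 1)
        assert fit.uniquenesses.min() >= 1e-3

    def test_invalid_f_rejected(self):
        Xc = np.zeros((5, 10))
        with pytest.raises(ValueError):
            fit_latent_fa(Xc, 5)
        with pytest.raises(ValueError):
            fit_latent_fa(Xc, -1)


class TestSelectNFactors:
    def test_singleton_range(self):
        rng = np.random.default_rng(8)
        Xc, _ = center(rng.random((10, 50)))
        best, table = select_n_factors(Xc, [1])
        assert best == 1 and len(table) == 1

    def test_smallest_f_at_min_bic(self):
        """Strong 2-factor data: BIC picks 2, and ties resolve downward."""
        rng = np.random.default_rng(9)
        m, n = 20, 600
        L0 = np.zeros((m, 2))
        L0[: m // 2, 0] = 1.5
        L0[m // 2 :, 1] = 1.5
        X = L0 @ rng.normal(size=(2, n)) + 0.4 * rng.normal(size=(m, n))
        Xc, _ = center(X)
        best, table = select_n_factors(Xc, range(1, 5))
        assert best == 2
        assert table["bic"].idxmin() == 1


class TestPredictAndMse:
    def test_zero_scores_predict_mu(self):
        mu = np.array([0.2, 0.8])
        pred = predict_responses(np.zeros((2, 3)), np.zeros((3, 4)), mu)
        np.testing.assert_allclose(pred, mu[:, None] * np.ones((1, 4)))

    def test_identity_reconstruction_and_zero_mse(self):
        rng = np.random.default_rng(10)
        X = (rng.random((6, 9)) < 0.5).astype(float)
        Xc, mu = center(X)
        pred = predict_responses(np.eye(6), Xc, mu)
        np.testing.assert_allclose(pred, X, atol=1e-12)
        assert mse_summary(X, pred).group_mse == pytest.approx(0.0, abs=1e-24)

    def test_toy_hand_product(self):
        L = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        F = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
        mu = np.array([0.1, 0.2, 0.3, 0.4])
        pred = predict_responses(L, F, mu)
        expected = mu[:, None] + np.array(
            [[1, 0, 2], [0, 1, 1], [1, 1, 3], [2, 0, 4]], float
        )
        np.testing.assert_allclose(pred, expected)

    def test_single_cell_squared_error(self):
        s = mse_summary(np.array([[1.0]]), np.array([[0.5]]))
        assert s.group_mse == pytest.approx(0.25)

    def test_mu_predictor_matches_bernoulli_variance(self):
        """Predicting mu gives group MSE ~ mean_i mu_i (1 - mu_i)."""
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, size=40)
        X = (rng.random((40, 5000)) < p[:, None]).astype(float)
        mu = X.mean(axis=1)
        pred = mu[:, None] * np.ones((1, 5000))
        s = mse_summary(X, pred, mode="mean_per_item")
        assert s.group_mse == pytest.approx(np.mean(p * (1 - p)), rel=0.02)

    def test_sum_mode_is_m_times_mean_mode(self):
        rng = np.random.default_rng(12)
        X = (rng.random((66, 20)) < 0.3).astype(float)
        pred = np.full_like(X, 0.3)
        s_mean = mse_summary(X, pred, mode="mean_per_item")
        s_sum = mse_summary(X, pred, mode="sum_over_items")
        np.testing.assert_allclose(
            s_sum.per_participant, 66 * s_mean.per_participant
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            mse_summary(np.zeros((2, 3)), np.zeros((3, 2)))


class TestCrossValidation:
    def test_fold_sizes_and_determinism(self):
        mem = make_folds(23, 5, seed=0)
        sizes = np.bincount(mem)
        assert sorted(sizes) == [4, 4, 4, 5, 5] or sorted(sizes.tolist()) == [4, 4, 5, 5, 5]
        np.testing.assert_array_equal(mem, make_folds(23, 5, seed=0))
        assert not np.array_equal(mem, make_folds(23, 5, seed=1))

    def test_noiseless_low_rank_held_out_mse(self):
        rng = np.random.default_rng(13)
        m, n, f = 24, 200, 3
        L0 = rng.normal(size=(m, f))
        X = L0 @ rng.normal(size=(f, n))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # Heywood expected
            s = cv_latent_mse(X, f=f, k=5, seed=0)
        assert s.group_mse < 0.01

    def test_seeded_determinism(self):
        rng = np.random.default_rng(14)
        X = (rng.random((30, 60)) < 0.3).astype(float)
        a = cv_latent_mse(X, f=2, k=5, seed=7)
        b = cv_latent_mse(X, f=2, k=5, seed=7)
        np.testing.assert_array_equal(a.per_participant, b.per_participant)

    def test_participant_permutation_invariance(self):
        """Permuting columns while carrying the fold membership along leaves
        the group MSE unchanged."""
        rng = np.random.default_rng(15)
        X = (rng.random((20, 40)) < 0.4).astype(float)
        mem = make_folds(40, 4, seed=3)
        perm = rng.permutation(40)

        from vizlit.factor_models import _cv_mse, fit_latent_fa

        def fit_l(Xc):
            return fit_latent_fa(Xc, 2).L

        # run CV manually with explicit membership on both orderings
        def run(Xv, member):
            per = np.empty(Xv.shape[1])
            for fold in range(4):
                test = member == fold
                train = ~test
                mu_t = Xv[:, train].mean(axis=1)
                L = fit_l(Xv[:, train] - mu_t[:, None])
                F = estimate_factor_scores(L, Xv[:, test] - mu_t[:, None])
                pred = predict_responses(L, F, mu_t)
                per[test] = ((Xv[:, test] - pred) ** 2).mean(axis=0)
            return per

        a = run(X, mem)
        b = run(X[:, perm], mem[perm])
        assert a.mean() == pytest.approx(b[np.argsort(perm)].mean(), abs=1e-10)

    def test_too_small_fold_rejected(self):
        X = np.zeros((10, 6))
        with pytest.raises(ValueError):
            cv_latent_mse(X, f=5, k=2, seed=0)


class TestInSampleMonotonicity:
    def test_adding_a_factor_never_hurts_in_sample(self):
        """In-sample latent MSE is non-increasing in f on random matrices."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = (rng.random((15, 80)) < rng.uniform(0.2, 0.5)).astype(float)
            Xc, mu = center(X)
            prev = np.inf
            for f in range(1, 5):
                fit = fit_latent_fa(Xc, f)
                F = estimate_factor_scores(fit.L, Xc)
                s = mse_summary(X, predict_responses(fit.L, F, mu))
                assert s.group_mse <= prev + 1e-9
                prev = s.group_mse


class TestCompareModels:
    def test_graph_generator_ranks_graph_model_best(self, bank):
        cfg = vz.SyntheticConfig(
            n_participants=250, loading_scheme="facet_indicator",
            facet="graph_type", loading_strength=2.0, ability_sd=0.0,
            math_effect=0.0, group_effect=0.0, incomplete_rate=0.0, seed=21,
        )
        _, _, truth = vz.generate_dataset(cfg)
        table = compare_factor_models(
            truth.X, bank, f_latent=4, seed=21, bootstrap_reps=500
        )
        ideal = table[table.model.str.startswith("idealized")]
        assert ideal.loc[ideal.group_mse.idxmin(), "model"] == "idealized_graph"

    def test_pure_noise_idealized_models_equivalent(self, bank):
        """With no factor structure the idealized models are equivalent once
        the mechanical fit from estimating f free scores per participant is
        removed: the df-adjusted residual variances m/(m-f) * MSE agree."""
        rng = np.random.default_rng(22)
        m = 66
        X = (rng.random((m, 400)) < 0.3).astype(float)
        table = compare_factor_models(X, bank, f_latent=1, seed=22,
                                      bootstrap_reps=2000)
        ideal = table[table.model.str.startswith("idealized")]
        adj = ideal["group_mse"] * m / (m - ideal["n_factors"])
        half_width = (ideal["ci_high"] - ideal["ci_low"]) / 2 * m / (
            m - ideal["n_factors"]
        )
        spread = adj.max() - adj.min()
        assert spread < half_width.max()

    def test_item_permutation_invariance(self, bank):
        rng = np.random.default_rng(23)
        X = (rng.random((66, 80)) < 0.35).astype(float)
        perm = rng.permutation(66)
        bank_p = vz.AssessmentBank(
            [bank.items[i] for i in perm], name="permuted"
        )
        for facet in ("test", "graph_type", "question_type"):
            a = idealized_mse(X, bank, facet).group_mse
            b = idealized_mse(X[perm], bank_p, facet).group_mse
            assert a == pytest.approx(b, abs=1e-12)


def test_varimax_preserves_communalities():
    rng = np.random.default_rng(24)
    L = rng.normal(size=(12, 3))
    Lr = varimax(L)
    np.testing.assert_allclose(
        (Lr**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8
    )
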