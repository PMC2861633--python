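import numpy as np
import pytest

from graphmer.data_prep import standardize
from graphmer.graph_pls import (
    PlsModel,
    fit_graph_pls,
    fit_simpls,
    nmse,
    predict,
    regress_latent,
)
from graphmer.kmer_graph import build_graph


def reference_simpls_first_weight(X, Y):
    """Independent oracle: the first SIMPLS weight is the leading left
    singular vector of X'Y (sign gauge: largest-|entry| of c positive)."""
    U, _, _ = np.linalg.svd(X.T @ Y, full_matrices=False)
    w = U[:, 0]
    c = Y.T @ (X @ w)
    c = c / np.linalg.norm(c)
    if c[np.argmax(np.abs(c))] < 0:
        w = -w
    return w


class TestSimpls:
    def test_first_weight_matches_svd_oracle(self, rng):
        X, _ = standardize(rng.normal(size=(10, 6)))
        Y, _ = standardize(rng.normal(size=(10, 2)))
        model = fit_simpls(X, Y, 1)
        np.testing.assert_allclose(
            model.W[:, 0], reference_simpls_first_weight(X, Y), atol=1e-10
        )

    def test_latent_factors_mutually_orthogonal(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 4)
        G = model.T.T @ model.T
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) <= 1e-6 * np.outer(norms, norms))

    def test_weights_unit_norm(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 4)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-6)

    def test_noiseless_linear_map_reaches_zero_training_nmse(self, rng):
        X, _ = standardize(rng.normal(size=(30, 5)))
        B = rng.normal(size=(5, 3))
        Y, _ = standardize(X @ B)
        model = fit_simpls(X, Y, 5)
        assert nmse(Y, predict(model, X)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_cross_covariance_stops_early(self):
        X = np.zeros((8, 4))
        Y = np.zeros((8, 2))
        with pytest.warns(UserWarning, match="exhausted"):
            model = fit_simpls(X, Y, 2)
        assert model.n_factors == 0

    def test_deterministic_given_inputs(self, std_xy):
        X, Y = std_xy
        a = fit_simpls(X, Y, 3)
        b = fit_simpls(X, Y, 3)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.B, b.B)


class TestGraphPls:
    def test_zero_penalties_reproduce_simpls(self, rng):
        # 20 random instances; max |difference| < 1e-6
        worst = 0.0
        for i in range(20):
            r = np.random.default_rng(100 + i)
            X, _ = standardize(r.normal(size=(20, 15)))
            Y, _ = standardize(r.normal(size=(20, 3)))
            ref = fit_simpls(X, Y, 3)
            got = fit_graph_pls(X, Y, 3, lambda_lasso=0.0, lambda_graph=0.0)
            worst = max(worst, np.abs(got.W - ref.W).max(),
                        np.abs(got.T - ref.T).max(), np.abs(got.C - ref.C).max())
        assert worst < 1e-6

    def test_strong_lasso_leaves_handful_of_nonzeros(self, std_xy):
        X, Y = std_xy
        model = fit_graph_pls(X, Y, 1, lambda_lasso=0.9, lambda_graph=0.0)
        assert np.count_nonzero(model.W[:, 0]) <= 5

    def test_nonzero_count_nonincreasing_in_lasso(self, std_xy):
        X, Y = std_xy
        nnz = []
        for ll in (0.1, 0.3, 0.5, 0.7, 0.9):
            m = fit_graph_pls(X, Y, 1, lambda_lasso=ll, lambda_graph=0.0)
            nnz.append(np.count_nonzero(m.W[:, 0]))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_smoothness_nonincreasing_in_graph_penalty(self, rng):
        kmers = ["AAAAAA", "AAAAAC", "AAAACC", "AAACCC", "AACCCC", "CCCCCC"]
        g = build_graph(kmers, theta=2)
        X, _ = standardize(rng.normal(size=(40, len(kmers))))
        Y, _ = standardize(rng.normal(size=(40, 3)) + X[:, :3])
        smooth = []
        for lg in (0.0, 0.5, 1.0, 2.0, 4.0):
            m = fit_graph_pls(X, Y, 1, lambda_lasso=0.0, lambda_graph=lg, graph=g)
            w = m.W[:, 0]
            smooth.append(float(w @ (g.laplacian @ w)))
        assert all(a >= b - 1e-9 for a, b in zip(smooth, smooth[1:]))

    def test_identical_columns_on_adjacent_nodes_get_equal_weights(self, rng):
        kmers = ["AAAAAA", "AAAAAC", "GGGGGG"]  # first two adjacent
        g = build_graph(kmers, theta=2)
        base = rng.normal(size=40)
        X = np.column_stack([base, base, rng.normal(size=40)])
        X, _ = standardize(X)
        Y, _ = standardize(np.outer(base, [1.0, -0.5]) + 0.05 * rng.normal(size=(40, 2)))
        m = fit_graph_pls(X, Y, 1, lambda_lasso=0.0, lambda_graph=1.0, graph=g)
        assert m.W[0, 0] == pytest.approx(m.W[1, 0], abs=1e-6)

    def test_missing_graph_rejected(self, std_xy):
        X, Y = std_xy
        with pytest.raises(ValueError, match="requires"):
            fit_graph_pls(X, Y, 1, lambda_graph=1.0)

    def test_bit_identical_reruns(self, std_xy):
        X, Y = std_xy
        a = fit_graph_pls(X, Y, 2, lambda_lasso=0.3, lambda_graph=0.0)
        b = fit_graph_pls(X, Y, 2, lambda_lasso=0.3, lambda_graph=0.0)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.B, b.B)


class TestRegressionAndPrediction:
    def test_orthogonal_factors_give_per_factor_coefficients(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 3)
        B = regress_latent(Y, model.T)
        for k in range(3):
            t = model.T[:, k]
            np.testing.assert_allclose(B[k], t @ Y / (t @ t), atol=1e-8)

    def test_zero_factors_predict_column_means(self, std_xy):
        X, Y = std_xy
        B = regress_latent(Y, np.zeros((X.shape[0], 0)))
        assert B.shape == (0, Y.shape[1])
        # on the standardized scale the zero prediction is the column-mean
        # predictor, whose NMSE is 1 by construction
        assert nmse(Y, np.zeros_like(Y)) == pytest.approx(1.0, abs=1e-12)

    def test_ridge_limit_matches_ols(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 3)
        ols = regress_latent(Y, model.T)
        ridge = regress_latent(Y, model.T, ridge_eps=1e-12)
        np.testing.assert_allclose(ridge, ols, atol=1e-6)

    def test_rank_deficient_factors_fall_back_to_ridge(self, std_xy):
        X, Y = std_xy
        T = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            B = regress_latent(Y, T)
        assert np.all(np.isfinite(B))

    def test_training_prediction_equals_latent_regression(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 3)
        np.testing.assert_allclose(
            predict(model, X), model.T @ model.B_inner, atol=1e-8
        )

    def test_prediction_is_explicit_matrix_product(self, rng):
        X, _ = standardize(rng.normal(size=(3, 4)))
        Y, _ = standardize(rng.normal(size=(3, 2)))
        model = fit_simpls(X, Y, 1)
        np.testing.assert_allclose(predict(model, X), X @ model.B, atol=1e-12)

    def test_all_mean_promoter_predicts_zero(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 2)
        np.testing.assert_array_equal(predict(model, np.zeros((1, X.shape[1]))), 0.0)

    def test_feature_mismatch_rejected(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 2)
        with pytest.raises(ValueError):
            predict(model, X[:, :-1])


class TestNmse:
    def test_column_mean_predictor_scores_one(self, rng):
        Y = rng.normal(size=(20, 3))
        Y_hat = np.tile(Y.mean(axis=0), (20, 1))
        assert nmse(Y, Y_hat) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_prediction_scores_zero(self, rng):
        Y = rng.normal(size=(10, 2))
        assert nmse(Y, Y) == 0.0

    def test_hand_computed_value(self):
        Y = np.array([[1.0], [2.0], [3.0]])
        Y_hat = np.ones((3, 1))
        assert nmse(Y, Y_hat) == pytest.approx(2.5)

    def test_constant_target_undefined(self):
        with pytest.raises(ValueError):
            nmse(np.ones((4, 2)), np.zeros((4, 2)))

    def test_training_nmse_nonincreasing_in_k(self, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 5)
        errors = []
        for K in range(1, 6):
            B = regress_latent(Y, model.T[:, :K])
            errors.append(nmse(Y, model.T[:, :K] @ B))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))


class TestSerialization:
    def test_model_directory_roundtrip(self, tmp_path, std_xy):
        X, Y = std_xy
        model = fit_simpls(X, Y, 3)
        model.meta["note"] = "test"
        model.save(tmp_path / "model")
        back = PlsModel.load(tmp_path / "model")
        for name in ("W", "T", "C", "U", "P", "B_inner", "B"):
            np.testing.assert_allclose(
                getattr(back, name), getattr(model, name), atol=1e-12
            )
        assert back.meta["note"] == "test"
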