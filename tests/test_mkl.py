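"""SVM/MKL training: analytic solutions, convergence, weights, serialization."""

import numpy as np
import pytest

from enhancerscan import (
    KernelMatrix,
    TrainConfig,
    decision_scores,
    linear_feature_weights,
    load_model,
    save_model,
    train_mkl,
    train_svm,
)
from enhancerscan.kernels import gram_matrix, variance_normalize
from enhancerscan.mkl import MKLModel, class_costs, kkt_residual


def make_signal_noise(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    X_signal = y[:, None] * 1.0 + 0.3 * rng.normal(size=(n, 2))
    X_noise = rng.normal(size=(n, 5))
    Ks = [
        variance_normalize(gram_matrix(X_signal, "signal")),
        variance_normalize(gram_matrix(X_noise, "noise")),
    ]
    return Ks, y, X_signal, X_noise


class TestTrainSvm:
    def test_two_point_analytic_solution(self):
        # x1=(1,0) y=+1, x2=(0,1) y=-1 under a linear kernel: K = I.
        # The dual has lambda_1 = lambda_2 = 1, so alpha = (+1,-1), b = 0,
        # and f(x1) = +1.
        K = KernelMatrix("linear", np.eye(2))
        model = train_svm(K, np.array([1, -1]), TrainConfig(C=10.0))
        assert model.alphas == pytest.approx([1.0, -1.0], abs=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        scores = decision_scores(model, [np.eye(2)])
        assert scores == pytest.approx([1.0, -1.0], abs=1e-6)

    def test_duplicated_dataset_leaves_decision_function_unchanged(self):
        # well-separated classes: the optimum sits strictly below the box
        # constraints, where duplicating every example changes nothing
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3)) + np.repeat([[4.0], [-4.0]], 10, axis=0)
        y = np.repeat([1, -1], 10)
        cfg = TrainConfig(C=100.0)
        K1 = variance_normalize(gram_matrix(X))
        m1 = train_svm(K1, y, cfg)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        K2 = variance_normalize(gram_matrix(X2))
        m2 = train_svm(K2, y2, cfg)
        probe = rng.normal(size=(7, 3))
        s1 = decision_scores(m1, [probe @ X.T / K1.normalizer])
        s2 = decision_scores(m2, [probe @ X2.T / K2.normalizer])
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_class_balanced_costs_closed_form(self):
        labels = np.array([1] * 10 + [-1] * 90)
        costs = class_costs(labels, C=1.0)
        assert costs[1] == pytest.approx(5.0)
        assert costs[-1] == pytest.approx(100 / 180)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            train_svm(KernelMatrix("k", np.eye(3)), np.array([1, 1, 1]))

    def test_kkt_residual_small_at_termination(self):
        Ks, y, _, _ = make_signal_noise(seed=3)
        model = train_svm(Ks[0], y)
        assert kkt_residual(model, [Ks[0]]) <= 1e-6


class TestTrainMkl:
    def test_single_kernel_reduces_to_svm(self):
        Ks, y, _, _ = make_signal_noise(seed=4)
        svm = train_svm(Ks[0], y)
        mkl = train_mkl([Ks[0]], y)
        assert mkl.betas == pytest.approx([1.0])
        assert mkl.alphas == pytest.approx(svm.alphas, abs=1e-8)
        assert mkl.bias == pytest.approx(svm.bias, abs=1e-8)

    def test_duplicated_kernels_match_single_kernel_objective(self):
        Ks, y, _, _ = make_signal_noise(seed=5)
        K = Ks[0]
        single = train_svm(K, y)
        double = train_mkl([K, KernelMatrix("copy", K.values, K.normalizer)], y)
        assert double.objective_path[-1] == pytest.approx(
            single.objective_path[-1], rel=1e-6
        )

    def test_signal_kernel_dominates_noise_kernel(self):
        Ks, y, _, _ = make_signal_noise(n=60, seed=0)
        model = train_mkl(Ks, y, TrainConfig(seed=0))
        assert model.kernel_names[0] == "signal"
        assert model.betas[0] > 0.9

    def test_objective_non_increasing(self):
        Ks, y, _, _ = make_signal_noise(seed=6)
        model = train_mkl(Ks, y)
        path = model.objective_path
        assert all(b <= a + 1e-9 * max(1, abs(a)) for a, b in zip(path, path[1:]))

    def test_invariants_of_trained_model(self):
        Ks, y, _, _ = make_signal_noise(seed=7)
        model = train_mkl(Ks, y)
        assert np.all(model.betas >= 0)
        assert model.betas.sum() == pytest.approx(1.0, abs=1e-6)
        assert model.alphas.sum() == pytest.approx(0.0, abs=1e-6)
        costs = class_costs(y, C=model.C)
        caps = np.where(y == 1, costs[1], costs[-1])
        assert np.all(np.abs(model.alphas) <= caps + 1e-8)

    def test_kernel_scale_invariance_of_prediction_signs(self):
        Ks, y, _, _ = make_signal_noise(seed=8)
        scale = 7.0
        scaled = [KernelMatrix(K.name, K.values * scale, K.normalizer) for K in Ks]
        m1 = train_mkl(Ks, y, TrainConfig(C=1.0))
        m2 = train_mkl(scaled, y, TrainConfig(C=1.0 / scale))
        s1 = decision_scores(m1, [K.values for K in Ks])
        s2 = decision_scores(m2, [K.values for K in scaled])
        assert np.array_equal(np.sign(s1), np.sign(s2))


class TestDecisionScores:
    def test_all_zero_alphas_give_bias(self):
        model = MKLModel(
            alphas=np.zeros(4), betas=np.array([1.0]), bias=0.37,
            labels=np.array([1, 1, -1, -1]), kernel_names=["k"],
            kernel_families=["linear"], normalizers=[1.0], train_refs=[], C=1.0,
        )
        assert decision_scores(model, [np.ones((5, 4))]) == pytest.approx([0.37] * 5)

    def test_training_set_separable_signs_match_labels(self):
        Ks, y, _, _ = make_signal_noise(seed=9)
        model = train_mkl(Ks, y)
        scores = decision_scores(model, [K.values for K in Ks])
        assert np.array_equal(np.sign(scores), y)

    def test_matrix_path_equals_explicit_double_sum(self):
        Ks, y, Xs, Xn = make_signal_noise(n=20, seed=10)
        model = train_mkl(Ks, y)
        blocks = [K.values for K in Ks]
        fast = decision_scores(model, blocks)
        slow = np.array([
            sum(
                model.alphas[i] * sum(
                    model.betas[j] * blocks[j][t, i] for j in range(2)
                )
                for i in range(20)
            ) + model.bias
            for t in range(20)
        ])
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_block_shape_mismatch_errors(self):
        Ks, y, _, _ = make_signal_noise(seed=11)
        model = train_mkl(Ks, y)
        with pytest.raises(ValueError):
            decision_scores(model, [np.ones((3, 5)), np.ones((3, 5))])


class TestLinearFeatureWeights:
    def test_zero_alphas_give_zero_weights(self):
        model = MKLModel(
            alphas=np.zeros(3), betas=np.array([1.0]), bias=0.0,
            labels=np.array([1, -1, 1]), kernel_names=["functional"],
            kernel_families=["linear"], normalizers=[2.0], train_refs=[], C=1.0,
        )
        w = linear_feature_weights(model, {"functional": np.ones((3, 4))})
        assert np.allclose(w["functional"], 0)

    def test_informative_feature_has_largest_weight(self):
        rng = np.random.default_rng(12)
        n = 40
        y = np.repeat([1, -1], n // 2)
        X = (rng.random(size=(n, 6)) < 0.3).astype(float)
        X[:, 2] = (y == 1).astype(float)  # single informative bit
        K = variance_normalize(gram_matrix(X, "functional"))
        model = train_mkl([K], y, families=["linear"])
        w = linear_feature_weights(model, {"functional": X})["functional"]
        assert np.argmax(np.abs(w)) == 2

    def test_scores_reconstructed_from_weights(self):
        rng = np.random.default_rng(13)
        n = 30
        y = np.repeat([1, -1], n // 2)
        X = rng.normal(size=(n, 5)) + y[:, None]
        K = variance_normalize(gram_matrix(X, "lin"))
        model = train_mkl([K], y, families=["linear"])
        w = linear_feature_weights(model, {"lin": X})["lin"]
        direct = decision_scores(model, [K.values])
        rebuilt = X @ w + model.bias
        assert rebuilt == pytest.approx(direct, abs=1e-9)

    def test_spectrum_kernel_refused(self):
        model = MKLModel(
            alphas=np.zeros(2), betas=np.array([1.0]), bias=0.0,
            labels=np.array([1, -1]), kernel_names=["spectrum"],
            kernel_families=["spectrum"], normalizers=[1.0], train_refs=[], C=1.0,
        )
        with pytest.raises(ValueError, match="spectrum"):
            linear_feature_weights(model, {"spectrum": np.ones((2, 16))})


class TestSerialization:
    def test_round_trip_reproduces_scores_bit_identically(self, tmp_path):
        Ks, y, Xs, Xn = make_signal_noise(seed=14)
        model = train_mkl(
            Ks, y,
            train_refs=[f"r{i}" for i in range(len(y))],
            train_features={"signal": Xs, "noise": Xn},
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        rng = np.random.default_rng(15)
        probe = {"signal": rng.normal(size=(9, 2)), "noise": rng.normal(size=(9, 5))}
        assert np.array_equal(model.score_features(probe), loaded.score_features(probe))
        assert loaded.kernel_names == model.kernel_names
        assert loaded.train_refs == model.train_refs
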