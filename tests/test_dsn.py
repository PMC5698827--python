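import numpy as np
import pytest

from orfstack.dsn import (
    DsnModel,
    FineTuneConfig,
    RbmConfig,
    TrainConfig,
    error_gradient,
    fine_tune_W,
    fit_upper_weights,
    forward,
    load_model,
    module_error,
    one_hot,
    predict,
    save_model,
    sigmoid,
    stack_input,
    train_dsn,
    train_rbm,
    rbm_reconstruction_error,
)


def two_gaussians(rng, n=400, d=10, sep=3.0):
    X = rng.normal(size=(n, d))
    y = np.array(["noncoding"] * (n // 2) + ["coding"] * (n // 2))
    X[y == "coding", 0] += sep
    return X, y


class TestStackInput:
    def test_first_module_is_raw_plus_bias(self, rng):
        X = rng.normal(size=(7, 5))
        Xm = stack_input(X, [])
        assert Xm.shape == (8, 5)
        np.testing.assert_array_equal(Xm[:7], X)
        np.testing.assert_array_equal(Xm[7], np.ones(5))

    def test_third_module_dimension(self, rng):
        X = rng.normal(size=(119, 4))
        outs = [rng.normal(size=(2, 4)), rng.normal(size=(2, 4))]
        assert stack_input(X, outs).shape == (124, 4)

    def test_column_order_preserved(self, rng):
        X = rng.normal(size=(3, 6))
        np.testing.assert_array_equal(stack_input(X, [])[:3], X)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            stack_input(rng.normal(size=(3, 6)), [rng.normal(size=(2, 5))])


class TestFitUpperWeights:
    def test_square_invertible_exact(self, rng):
        H = rng.normal(size=(6, 6)) + 6 * np.eye(6)
        T = rng.normal(size=(2, 6))
        U = fit_upper_weights(H, T, ridge_eps=0.0)
        np.testing.assert_allclose(U.T @ H, T, atol=1e-8)

    def test_matches_lstsq_oracle(self, rng):
        H = rng.normal(size=(6, 40))
        T = rng.normal(size=(2, 40))
        U = fit_upper_weights(H, T, ridge_eps=0.0)
        U_oracle = np.linalg.lstsq(H.T, T.T, rcond=None)[0]
        np.testing.assert_allclose(U, U_oracle, atol=1e-8)

    def test_optimality_under_random_perturbations(self, rng):
        H = sigmoid(rng.normal(size=(5, 30)))
        T = one_hot(rng.choice(["coding", "noncoding"], size=30))
        U = fit_upper_weights(H, T, ridge_eps=0.0)
        E = np.sum((U.T @ H - T) ** 2)
        for _ in range(1000):
            dU = rng.normal(scale=10 ** rng.uniform(-4, 0), size=U.shape)
            E_pert = np.sum(((U + dU).T @ H - T) ** 2)
            assert E <= E_pert + 1e-12


class TestGradient:
    def test_matches_central_finite_differences(self, rng):
        D, L, N, C = 5, 4, 8, 2
        X = np.vstack([rng.normal(size=(D - 1, N)), np.ones((1, N))])
        T = one_hot(rng.choice(["coding", "noncoding"], size=N))
        W = rng.normal(scale=0.5, size=(D, L))
        eps_ridge = 1e-10
        grad = error_gradient(W, X, T, eps_ridge)

        def objective(Wx):
            # ridge objective actually minimized over U (envelope theorem)
            H = sigmoid(Wx.T @ X)
            U = fit_upper_weights(H, T, eps_ridge)
            return np.sum((U.T @ H - T) ** 2) + eps_ridge * np.sum(U**2)

        h = 1e-6
        fd = np.zeros_like(W)
        for i in range(D):
            for j in range(L):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += h
                Wm[i, j] -= h
                fd[i, j] = (objective(Wp) - objective(Wm)) / (2 * h)
        rel = np.abs(grad - fd) / (np.abs(fd).max() + 1e-12)
        assert rel.max() < 1e-5

    def test_non_finite_input_raises(self):
        W = np.full((3, 2), 1e300)
        X = np.full((3, 4), 1e300)
        T = one_hot(["coding", "noncoding", "coding", "noncoding"])
        with pytest.raises((FloatingPointError, ValueError)):
            error_gradient(W, X, T, 1e-8)


class TestFineTune:
    def test_error_never_increases(self, rng):
        D, L, N = 12, 6, 60
        X = np.vstack([rng.normal(size=(D - 1, N)), np.ones((1, N))])
        T = one_hot(rng.choice(["coding", "noncoding"], size=N))
        W0 = rng.normal(scale=0.3, size=(D, L))
        E0, _ = module_error(W0, X, T, 1e-8)
        W = W0
        for _ in range(5):
            W = fine_tune_W(W, X, T, learning_rate=1e-3, epochs=4, ridge_eps=1e-8)
            E, _ = module_error(W, X, T, 1e-8)
            assert E <= E0 + 1e-10
            E0 = E

    def test_descends_on_fixed_problem(self, rng):
        D, L, N = 8, 5, 40
        X = np.vstack([rng.normal(size=(D - 1, N)), np.ones((1, N))])
        T = one_hot(rng.choice(["coding", "noncoding"], size=N))
        W0 = rng.normal(scale=0.3, size=(D, L))
        E0, _ = module_error(W0, X, T, 1e-8)
        W1 = fine_tune_W(W0, X, T, learning_rate=1e-2, epochs=30, ridge_eps=1e-8)
        E1, _ = module_error(W1, X, T, 1e-8)
        assert E1 < E0

    def test_invalid_learning_rate(self, rng):
        with pytest.raises(ValueError):
            fine_tune_W(np.zeros((2, 2)), np.ones((2, 3)), np.ones((2, 3)), 0.0, 1)


class TestRbm:
    def test_deterministic_given_seed(self, rng):
        X = rng.random((6, 80))
        cfg = RbmConfig(epochs=3, batch_size=20)
        W1 = train_rbm(X, 4, cfg, np.random.default_rng(9))
        W2 = train_rbm(X, 4, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(W1, W2)

    def test_reconstruction_improves_on_two_clusters(self, rng):
        n = 200
        centers = rng.random((2, 12)) > 0.5
        X = np.vstack(
            [centers[i % 2] ^ (rng.random(12) < 0.05) for i in range(n)]
        ).T.astype(float)
        cfg = RbmConfig(epochs=10, batch_size=20, learning_rate=0.2)
        rng_init = np.random.default_rng(3)
        W_init = np.vstack([rng_init.normal(0, 0.01, size=(12, 6)), np.zeros((1, 6))])
        W = train_rbm(X, 6, cfg, np.random.default_rng(3))
        assert rbm_reconstruction_error(X, W) < rbm_reconstruction_error(X, W_init)

    def test_zero_hidden_units_is_error(self, rng):
        with pytest.raises(ValueError):
            train_rbm(rng.random((4, 10)), 0, RbmConfig(), rng)


FAST = TrainConfig(
    n_modules=1,
    hidden_units=16,
    rbm=RbmConfig(epochs=3, batch_size=50),
    fine_tune=FineTuneConfig(enabled=True, learning_rate=1e-3, epochs=5),
    seed=7,
)


class TestTrainPredict:
    def test_separable_gaussians_high_accuracy(self, rng):
        X, y = two_gaussians(rng)
        model = train_dsn(X, y, FAST)
        labels, scores = predict(model, X)
        assert np.mean(labels == y) >= 0.95
        assert scores.shape == (400, 2)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_shuffled_labels_cv_is_chance(self, biased_dataset):
        from orfstack.evaluation import kfold_cv

        X, y = biased_dataset
        y_shuf = y.copy()
        np.random.default_rng(11).shuffle(y_shuf)
        res = kfold_cv(
            X,
            y_shuf,
            lambda Xt, yt: train_dsn(Xt, yt, FAST),
            lambda m, Xt: predict(m, Xt)[0],
            k=10,
            seed=12,
        )
        acc = res.summary()["acc"][0]
        assert 0.45 <= acc <= 0.55

    def test_deterministic_model_file(self, rng, tmp_path):
        X, y = two_gaussians(rng, n=120)
        p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
        save_model(train_dsn(X, y, FAST), p1)
        save_model(train_dsn(X, y, FAST), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_class_is_error(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_dsn(X, ["coding"] * 10)

    def test_identical_inputs_identical_scores(self, rng):
        X, y = two_gaussians(rng, n=100)
        model = train_dsn(X, y, FAST)
        Xq = np.repeat(X[:1], 2, axis=0)
        _, scores = predict(model, Xq)
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_dimension_mismatch_is_error(self, rng):
        X, y = two_gaussians(rng, n=100)
        model = train_dsn(X, y, FAST)
        with pytest.raises(ValueError, match="features"):
            predict(model, rng.normal(size=(4, 7)))

    def test_monotone_stacking_error(self, biased_dataset):
        # empirical property: each stacked module fits the training
        # targets at least as well as the previous one (1% slack)
        X, y = biased_dataset
        cfg = TrainConfig(
            n_modules=3,
            hidden_units=32,
            rbm=RbmConfig(epochs=3),
            fine_tune=FineTuneConfig(enabled=True, epochs=5),
            seed=3,
        )
        model = train_dsn(X, y, cfg)
        from orfstack.dsn import one_hot, stack_input, sigmoid

        T = one_hot(y)
        Xs = model.scaler.zscore(X).T
        outputs = []
        errors = []
        for params in model.modules:
            Xm = stack_input(Xs, outputs)
            H = sigmoid(params.W.T @ Xm)
            Y = params.U.T @ H
            errors.append(float(np.sum((Y - T) ** 2)))
            outputs.append(Y)
        for e_prev, e_next in zip(errors, errors[1:]):
            assert e_next <= 1.01 * e_prev

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = two_gaussians(rng, n=100)
        model = train_dsn(X, y, FAST)
        path = tmp_path / "m.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(forward(model, X), forward(loaded, X))
        assert loaded.config == model.config

    def test_unknown_model_version_rejected(self, rng, tmp_path):
        X, y = two_gaussians(rng, n=100)
        model = train_dsn(X, y, FAST)
        model.version = 999
        path = tmp_path / "m.npz"
        save_model(model, path)
        with pytest.raises(ValueError, match="version"):
            load_model(path)
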