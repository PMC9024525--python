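"""Forward/backward correctness of the shared-injection network.

The central oracle is the finite-difference gradient check: the analytic
backpropagation — including the summed gradient of the shared input
projection across its three injection sites — must match central
differences of the loss.
"""

import numpy as np
import pytest

from respmotion import network as nw


def _random_batch(head, n=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 33))
    if head == "classifier":
        Y = np.zeros((n, 10))
        Y[np.arange(n), rng.integers(0, 10, n)] = 1.0
    else:
        Y = rng.uniform(0, 1, size=(n, 1))
    return X, Y


def _numeric_gradient(params, X, Y, l1, eps=1e-6):
    vec = nw.params_to_vector(params)
    num = np.zeros_like(vec)
    for i in range(len(vec)):
        vp, vm = vec.copy(), vec.copy()
        vp[i] += eps
        vm[i] -= eps
        num[i] = (
            nw.loss(nw.vector_to_params(vp, params), X, Y, l1)
            - nw.loss(nw.vector_to_params(vm, params), X, Y, l1)
        ) / (2 * eps)
    return num


class TestInit:
    @pytest.mark.parametrize("head,out_dim", [("classifier", 10), ("regressor", 1)])
    def test_shapes(self, head, out_dim):
        p = nw.init_params(head, seed=0)
        assert p.w_in.shape == (11, 8)
        widths = nw.HIDDEN_WIDTHS
        for k, w in enumerate(p.hidden_w):
            assert w.shape == (widths[k], widths[k + 1])
        assert p.w_out.shape == (5, out_dim)

    def test_seed_reproducibility(self):
        a, b = nw.init_params("classifier", 3), nw.init_params("classifier", 3)
        assert np.array_equal(nw.params_to_vector(a), nw.params_to_vector(b))

    def test_invalid_head(self):
        with pytest.raises(ValueError):
            nw.init_params("autoencoder", 0)


class TestForward:
    def test_zero_params_classifier_uniform(self):
        p = nw.init_params("classifier", 0)
        for a in p.all_arrays():
            a[...] = 0.0
        out = nw.forward(p, np.zeros((3, 33))).output
        assert np.allclose(out, 0.1)

    def test_zero_params_regressor_zero(self):
        p = nw.init_params("regressor", 0)
        for a in p.all_arrays():
            a[...] = 0.0
        assert np.allclose(nw.forward(p, np.zeros((2, 33))).output, 0.0)

    def test_softmax_normalization_and_ranges(self):
        p = nw.init_params("classifier", 1)
        X, _ = _random_batch("classifier", n=16, seed=2)
        tr = nw.forward(p, X)
        assert np.allclose(tr.output.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((tr.output > 0) & (tr.output < 1))
        for a in tr.a:
            assert np.all(np.abs(a) <= 1.0)

    def test_relu_nonnegative(self):
        p = nw.init_params("regressor", 1)
        X, _ = _random_batch("regressor", n=16, seed=3)
        assert np.all(nw.forward(p, X).output >= 0.0)

    def test_shared_injection_reaches_deep_layers(self):
        # zero the T-2 and T-1 blocks: the T0 block still changes the output
        # only through the shared matrix injected at hidden layer 5
        p = nw.init_params("classifier", 4)
        X = np.zeros((1, 33))
        base = nw.forward(p, X).output
        X2 = X.copy()
        X2[0, 22:] = 1.0
        assert not np.allclose(nw.forward(p, X2).output, base)

    def test_shape_mismatch_rejected(self):
        p = nw.init_params("classifier", 0)
        with pytest.raises(ValueError, match="33"):
            nw.forward(p, np.zeros((2, 12)))


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        # regressor whose output equals the target has zero data loss
        p = nw.init_params("regressor", 5)
        X, _ = _random_batch("regressor", n=3, seed=5)
        Y = nw.forward(p, X).output
        assert nw.loss(p, X, Y, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_uniform_classifier_loss_is_ln10(self):
        p = nw.init_params("classifier", 0)
        for a in p.all_arrays():
            a[...] = 0.0
        X, Y = _random_batch("classifier", n=6, seed=1)
        assert nw.loss(p, X, Y, 0.0) == pytest.approx(np.log(10.0), rel=1e-12)

    def test_l1_zero_gives_pure_data_loss(self):
        p = nw.init_params("classifier", 2)
        X, Y = _random_batch("classifier", seed=4)
        assert nw.loss(p, X, Y, 0.0) < nw.loss(p, X, Y, 1e-2)


class TestBackward:
    @pytest.mark.parametrize("head", ["classifier", "regressor"])
    @pytest.mark.parametrize("l1", [0.0, 1e-4])
    def test_gradient_matches_finite_differences(self, head, l1):
        p = nw.init_params(head, seed=3)
        X, Y = _random_batch(head, n=4, seed=0)
        analytic = nw.params_to_vector(nw.backward(p, X, Y, l1))
        numeric = _numeric_gradient(p, X, Y, l1)
        denom = np.maximum(np.maximum(np.abs(numeric), np.abs(analytic)), 1e-8)
        assert np.max(np.abs(numeric - analytic) / denom) < 1e-5

    def test_stationary_output_bias_at_loss_minimum(self):
        # targets equal to the current outputs: zero output-bias gradient
        p = nw.init_params("classifier", 7)
        X, _ = _random_batch("classifier", n=5, seed=7)
        Y = nw.forward(p, X).output
        g = nw.backward(p, X, Y, 0.0)
        assert np.allclose(g.b_out, 0.0, atol=1e-12)

    def test_shared_gradient_equals_sum_of_untied_copies(self):
        """Untie the input projection into three independent matrices; the
        shared-weight gradient must equal the sum of the three copies'."""
        p = nw.init_params("classifier", 11)
        X, Y = _random_batch("classifier", n=4, seed=11)
        x2, x1, x0 = X[:, :11], X[:, 11:22], X[:, 22:]

        def untied_loss(W1, W2, W3):
            z = x2 @ W1 + p.b_in
            a = np.tanh(z)
            for k in range(1, 7):
                z = a @ p.hidden_w[k - 1] + p.hidden_b[k - 1]
                if k == 2:
                    z = z + x1 @ W2
                if k == 4:
                    z = z + x0 @ W3
                a = np.tanh(z)
            zo = a @ p.w_out + p.b_out
            e = np.exp(zo - zo.max(axis=1, keepdims=True))
            prob = e / e.sum(axis=1, keepdims=True)
            return -np.sum(Y * np.log(prob)) / len(X)

        eps = 1e-6
        total = np.zeros_like(p.w_in)
        for site in range(3):
            for i in range(11):
                for j in range(8):
                    mats_p = [p.w_in.copy() for _ in range(3)]
                    mats_m = [p.w_in.copy() for _ in range(3)]
                    mats_p[site][i, j] += eps
                    mats_m[site][i, j] -= eps
                    total[i, j] += (
                        untied_loss(*mats_p) - untied_loss(*mats_m)
                    ) / (2 * eps)
        analytic = nw.backward(p, X, Y, 0.0).w_in
        assert np.allclose(total, analytic, rtol=1e-4, atol=1e-7)


class TestTrain:
    def test_loss_decreases(self):
        X, Y = _random_batch("classifier", n=30, seed=1)
        cfg = nw.TrainingConfig(head="classifier", max_epochs=50, patience=50, seed=1)
        _, h = nw.train(X, Y, X, Y, cfg)
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_runs_all_epochs_without_divergence(self):
        X, Y = _random_batch("regressor", n=20, seed=2)
        cfg = nw.TrainingConfig(head="regressor", max_epochs=40, patience=100, seed=2)
        _, h = nw.train(X, Y, X, Y, cfg)
        assert h["n_epochs"] == 40

    def test_early_stop_on_divergent_test_loss(self):
        rng = np.random.default_rng(3)
        X_train, Y_train = _random_batch("classifier", n=20, seed=3)
        # disjoint distribution: test loss rises while train loss falls
        X_test = rng.normal(loc=5.0, size=(20, 33))
        Y_test = np.zeros((20, 10))
        Y_test[np.arange(20), rng.integers(0, 10, 20)] = 1.0
        cfg = nw.TrainingConfig(head="classifier", max_epochs=2000, patience=10, seed=3)
        params, h = nw.train(X_train, Y_train, X_test, Y_test, cfg)
        assert h["n_epochs"] < 2000
        assert h["best_epoch"] <= h["n_epochs"] - cfg.patience

    def test_bitwise_reproducible(self):
        X, Y = _random_batch("classifier", n=25, seed=5)
        cfg = nw.TrainingConfig(head="classifier", max_epochs=30, seed=5)
        p1, _ = nw.train(X, Y, X, Y, cfg)
        p2, _ = nw.train(X, Y, X, Y, cfg)
        assert np.array_equal(nw.params_to_vector(p1), nw.params_to_vector(p2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            nw.TrainingConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            nw.TrainingConfig(head="both")


class TestPredict:
    def test_argmax_rule(self):
        p = nw.init_params("classifier", 1)
        X, _ = _random_batch("classifier", n=8, seed=8)
        probs = nw.forward(p, X).output
        assert np.array_equal(nw.predict_phases(p, X), probs.argmax(axis=1))

    def test_head_mismatch_rejected(self):
        p = nw.init_params("regressor", 1)
        with pytest.raises(ValueError):
            nw.predict_phases(p, np.zeros((1, 33)))
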