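import numpy as np
import pytest

from lumigrain import bilstm
from lumigrain.bilstm import (
    BiLSTMModel,
    LSTMWeights,
    TrainConfig,
    backward,
    bilstm_forward,
    loss,
    lstm_step,
    predict,
    train,
)
from lumigrain.walsh import Codebook


def zero_weights(hidden=3, input_dim=1):
    shape = (hidden, hidden + input_dim)
    return LSTMWeights(*(np.zeros(shape) for _ in range(4)),
                       *(np.zeros(hidden) for _ in range(4)))


def fd_gradient_check(model, x, tgt, lam, n_train, rng, n_probes=6, eps=1e-5):
    """Central-difference oracle; returns flattened numeric/analytic pairs."""
    out, caches = bilstm_forward(model, x)
    grads = backward(model, caches, tgt, lam, n_train)
    nums, anas = [], []
    for key, p in model.parameters().items():
        flat = p.ravel()
        g = grads[key].ravel()
        probes = rng.choice(flat.size, size=min(n_probes, flat.size), replace=False)
        for idx in probes:
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss(bilstm_forward(model, x)[0], tgt, model, lam, n_train)
            flat[idx] = orig - eps
            lm = loss(bilstm_forward(model, x)[0], tgt, model, lam, n_train)
            flat[idx] = orig
            nums.append((lp - lm) / (2 * eps))
            anas.append(g[idx])
    return np.array(nums), np.array(anas)


class TestLSTMStep:
    def test_all_zero_weights_zero_state(self):
        w = zero_weights()
        y, s, cache = lstm_step(w, np.zeros((1, 1)), np.zeros((1, 3)), np.zeros((1, 3)))
        np.testing.assert_allclose(cache["i"], 0.5)
        np.testing.assert_allclose(cache["f"], 0.5)
        np.testing.assert_allclose(cache["o"], 0.5)
        np.testing.assert_allclose(cache["g"], 0.0)
        np.testing.assert_allclose(s, 0.0)
        np.testing.assert_allclose(y, 0.0)

    def test_all_zero_weights_carried_state(self):
        w = zero_weights()
        c = np.full((1, 3), 0.8)
        y, s, _ = lstm_step(w, np.zeros((1, 1)), np.zeros((1, 3)), c)
        np.testing.assert_allclose(s, 0.5 * c)
        np.testing.assert_allclose(y, 0.5 * np.tanh(0.5 * c))

    def test_matches_straight_line_reimplementation(self, rng):
        # independent duplicate evaluation of the gate equations
        w = LSTMWeights.init(4, 2, rng)
        x = rng.normal(size=(3, 2))
        y_prev = rng.normal(size=(3, 4))
        s_prev = rng.normal(size=(3, 4))
        y, s, _ = lstm_step(w, x, y_prev, s_prev)

        def sig(a):
            return 1.0 / (1.0 + np.exp(-a))

        for b in range(3):
            z = np.concatenate([y_prev[b], x[b]])
            i = sig(w.W_i @ z + w.b_i)
            f = sig(w.W_f @ z + w.b_f)
            o = sig(w.W_o @ z + w.b_o)
            g = np.tanh(w.W_c @ z + w.b_c)
            s_ref = f * s_prev[b] + i * g
            np.testing.assert_allclose(s[b], s_ref, rtol=1e-12)
            np.testing.assert_allclose(y[b], o * np.tanh(s_ref), rtol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        w = LSTMWeights.init(4, 2, rng)
        with pytest.raises(ValueError):
            lstm_step(w, np.zeros((1, 3)), np.zeros((1, 4)), np.zeros((1, 4)))


class TestForward:
    def test_zero_head_weights_give_uniform_softmax(self, rng):
        model = BiLSTMModel.init(4, 1, 5, "softmax_onehot", rng)
        model.W_head[:] = 0.0
        model.b_head[:] = 0.0
        out, _ = bilstm_forward(model, rng.normal(size=(10, 1)))
        np.testing.assert_allclose(out, 0.2)

    def test_palindrome_with_tied_weights_symmetric_states(self, rng):
        model = BiLSTMModel.init(4, 1, 5, "softmax_onehot", rng)
        model.backward_cell = model.forward_cell
        seq = np.array([1.0, 2.0, 3.0, 2.0, 1.0])[:, None]
        _, caches = bilstm_forward(model, seq)
        np.testing.assert_allclose(caches["h"][0, :4], caches["h"][0, 4:], rtol=1e-12)

    def test_softmax_outputs_sum_to_one(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
            out, _ = bilstm_forward(model, rng.normal(size=(6, 1)))
            assert out.sum() == pytest.approx(1.0)

    def test_empty_sequence_rejected(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        with pytest.raises(ValueError):
            bilstm_forward(model, np.zeros((0, 1)))


class TestLoss:
    def test_uniform_softmax_onehot_is_ln5(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        out = np.full(5, 0.2)
        tgt = np.eye(5)[0]
        assert loss(out, tgt, model, 0.0) == pytest.approx(np.log(5))

    def test_perfect_prediction_zero_loss(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        assert loss(np.eye(5)[2], np.eye(5)[2], model, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_l2_term_additivity(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        out = np.full(5, 0.2)
        tgt = np.eye(5)[1]
        lam, n = 0.7, 13
        base = loss(out, tgt, model, 0.0, n)
        reg = loss(out, tgt, model, lam, n)
        assert reg - base == pytest.approx(lam / (2 * n) * np.sum(model.W_head**2))

    def test_walsh_mode_per_bit_bce(self, rng):
        model = BiLSTMModel.init(3, 1, 8, "sigmoid_walsh", rng)
        tgt = Codebook(5, 8).codewords[1].astype(float)
        out = np.full(8, 0.5)
        assert loss(out, tgt, model, 0.0) == pytest.approx(8 * np.log(2))

    def test_shape_mismatch_rejected(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        with pytest.raises(ValueError):
            loss(np.zeros(5), np.zeros(8), model)


class TestBackward:
    @pytest.mark.parametrize("mode,out_dim", [("softmax_onehot", 5), ("sigmoid_walsh", 8)])
    def test_gradients_match_finite_differences(self, mode, out_dim):
        rng = np.random.default_rng(0)
        for _ in range(10):
            model = BiLSTMModel.init(4, 1, out_dim, mode, rng)
            x = rng.normal(size=(1, 10, 1))
            if mode == "softmax_onehot":
                tgt = np.eye(5)[[rng.integers(5)]]
            else:
                tgt = Codebook(5, 8).codewords[[rng.integers(5)]].astype(float)
            nums, anas = fd_gradient_check(model, x, tgt, 0.01, 7, rng)
            denom = max(np.linalg.norm(nums), np.linalg.norm(anas))
            assert np.linalg.norm(nums - anas) / denom < 1e-5

    def test_l2_gradient_alone(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        x = rng.normal(size=(1, 4, 1))
        tgt = np.eye(5)[[0]]
        _, caches = bilstm_forward(model, x)
        g0 = backward(model, caches, tgt, 0.0, 9)
        g1 = backward(model, caches, tgt, 2.0, 9)
        np.testing.assert_allclose(g1["head.W"] - g0["head.W"],
                                   (2.0 / 9) * model.W_head, rtol=1e-12)

    def test_stationary_at_perfect_prediction(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        x = rng.normal(size=(1, 4, 1))
        out, caches = bilstm_forward(model, x)
        # use the model's own output as target: dlogits == 0
        grads = backward(model, caches, out, 0.0, 1)
        assert np.abs(grads["head.W"]).max() == pytest.approx(0.0, abs=1e-12)

    def test_stale_caches_rejected(self, rng):
        model = BiLSTMModel.init(3, 1, 5, "softmax_onehot", rng)
        _, caches = bilstm_forward(model, rng.normal(size=(2, 4, 1)))
        with pytest.raises(ValueError, match="stale|match"):
            backward(model, caches, np.eye(5)[[0, 1, 2]])


class TestTrain:
    @pytest.fixture
    def separable(self, rng):
        X = np.vstack([rng.normal(-1, 0.3, (25, 10)), rng.normal(1, 0.3, (25, 10))])
        y = np.array([0] * 25 + [1] * 25)
        return X, y

    def test_separable_reaches_full_training_accuracy(self, separable):
        X, y = separable
        cfg = TrainConfig(hidden=16, epochs=50, learning_rate=5e-3,
                          feature_noise_sd=0.0, seed=0)
        model, hist = train(X, y, cfg)
        assert hist.accuracy[-1] == 1.0
        assert hist.loss[-1] < hist.loss[0]

    def test_same_seed_identical_weights_and_history(self, separable):
        X, y = separable
        cfg = TrainConfig(hidden=8, epochs=5, seed=3)
        m1, h1 = train(X, y, cfg)
        m2, h2 = train(X, y, cfg)
        assert h1.loss == h2.loss and h1.accuracy == h2.accuracy
        for a, b in zip(m1.parameters().values(), m2.parameters().values()):
            np.testing.assert_array_equal(a, b)

    def test_history_lengths_equal_epochs(self, separable):
        X, y = separable
        _, hist = train(X, y, TrainConfig(hidden=4, epochs=7, seed=0))
        assert len(hist.loss) == len(hist.accuracy) == 7

    def test_walsh_mode_training(self, separable):
        X, y = separable
        cfg = TrainConfig(hidden=16, epochs=50, learning_rate=5e-3,
                          feature_noise_sd=0.0, seed=0)
        model, hist = train(X, y, cfg, codebook=Codebook(5, 8))
        assert model.head_mode == "sigmoid_walsh"
        assert hist.accuracy[-1] >= 0.9

    def test_regularization_shrinks_head_norm(self, separable):
        X, y = separable
        norms = []
        for lam in (0.0, 0.1, 1.0, 10.0):
            cfg = TrainConfig(hidden=8, epochs=30, learning_rate=5e-3,
                              l2_lambda=lam, feature_noise_sd=0.0, seed=0)
            model, _ = train(X, y, cfg)
            norms.append(np.linalg.norm(model.W_head))
        assert norms == sorted(norms, reverse=True)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 10))
        with pytest.raises(ValueError):
            train(X, np.zeros(10, dtype=int), TrainConfig(hidden=4, epochs=1))


class TestPredict:
    def test_exact_codeword_decodes_to_class(self, rng):
        cb = Codebook(5, 8)
        model = BiLSTMModel.init(4, 1, 8, "sigmoid_walsh", rng)
        # force the head to emit near-codeword logits for one input
        from lumigrain.walsh import decode
        soft = cb.codewords[3].astype(float)
        cls, dist = decode(soft, cb)
        assert cls == 3 and dist == 0.0

    def test_argmax_tie_lowest_index(self):
        out = np.array([[0.4, 0.4, 0.2]])
        assert int(np.argmax(out, axis=1)[0]) == 0

    def test_order_invariance(self, rng):
        model = BiLSTMModel.init(8, 1, 5, "softmax_onehot", rng)
        X = rng.normal(size=(12, 10))
        preds = predict(model, X)
        perm = rng.permutation(12)
        preds_perm = predict(model, X[perm])
        np.testing.assert_array_equal(preds_perm, preds[perm])

    def test_walsh_model_without_codebook_rejected(self, rng):
        model = BiLSTMModel.init(4, 1, 8, "sigmoid_walsh", rng)
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(2, 10)))


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = BiLSTMModel.init(6, 1, 5, "softmax_onehot", rng)
        model.save(tmp_path / "model", extra_meta={"class_labels": ["a", "b"]})
        loaded, meta = BiLSTMModel.load(tmp_path / "model")
        assert meta["class_labels"] == ["a", "b"]
        assert loaded.head_mode == model.head_mode
        X = rng.normal(size=(4, 10))
        np.testing.assert_array_equal(predict(model, X), predict(loaded, X))
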