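"""LSTM cell math, forward pass, loss, training and splits."""

import math
import warnings

import numpy as np
import pytest

from modcaller.features import WindowSet
from modcaller.lstm import (
    BiLstmClassifier,
    LstmParams,
    ModelConfig,
    cross_entropy,
    lstm_cell,
    softmax,
    split_read_based,
    split_region_based,
)


def _cfg(**kw):
    kw.setdefault("w", 7)
    kw.setdefault("hidden_size", 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ModelConfig(**kw)


class TestLstmCell:
    def test_zero_weights_zero_states_give_zero_output(self):
        H = 3
        params = LstmParams(np.zeros((7, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H))
        p, v = lstm_cell(np.ones(7), np.zeros(H), np.zeros(H), params)
        np.testing.assert_allclose(p, 0.0)
        np.testing.assert_allclose(v, 0.0)

    def test_output_bounded_for_any_finite_input(self):
        rng = np.random.default_rng(0)
        H = 5
        params = LstmParams(rng.normal(0, 3, (7, 4 * H)), rng.normal(0, 3, (H, 4 * H)),
                            rng.normal(0, 3, 4 * H))
        p, _ = lstm_cell(rng.normal(0, 100, 7), rng.normal(0, 1, H), rng.normal(0, 5, H),
                         params)
        assert np.all(np.abs(p) < 1.0)

    def test_scalar_hand_evaluation_of_the_four_gates(self):
        # H = 1, every weight 1, biases 0, x = e_1, zero states:
        # each gate pre-activation is 1
        H = 1
        params = LstmParams(np.ones((7, 4)), np.ones((1, 4)), np.zeros(4))
        x = np.array([1.0, 0, 0, 0, 0, 0, 0])
        p, v = lstm_cell(x, np.zeros(1), np.zeros(1), params)
        sig1 = 1.0 / (1.0 + math.exp(-1.0))
        v_expected = math.tanh(1.0) * sig1
        p_expected = math.tanh(v_expected) * sig1
        assert v[0] == pytest.approx(v_expected, abs=1e-12)
        assert p[0] == pytest.approx(p_expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        params = LstmParams(np.zeros((7, 8)), np.zeros((2, 8)), np.zeros(8))
        with pytest.raises(ValueError):
            lstm_cell(np.zeros(5), np.zeros(2), np.zeros(2), params)


class TestForward:
    def test_softmax_sums_to_one_and_symmetry(self):
        rng = np.random.default_rng(1)
        probs = softmax(rng.normal(0, 5, (10, 2)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(softmax(np.array([2.0, 2.0])), [0.5, 0.5])

    def test_zero_initialized_network_outputs_half(self):
        m = BiLstmClassifier(_cfg(seed=0))
        m.zero_parameters()
        X = np.random.default_rng(2).normal(size=(5, 7, 7))
        np.testing.assert_allclose(m.forward_batch(X)[:, 1], 0.5, atol=1e-12)

    def test_deterministic_given_parameters(self):
        m = BiLstmClassifier(_cfg(seed=3))
        X = np.random.default_rng(4).normal(size=(4, 7, 7))
        np.testing.assert_array_equal(m.forward_batch(X), m.forward_batch(X))

    def test_width_mismatch_rejected(self):
        m = BiLstmClassifier(_cfg(seed=0))
        with pytest.raises(ValueError, match="does not match"):
            m.forward_batch(np.zeros((2, 9, 7)))
        with pytest.raises(ValueError, match="does not match"):
            m.forward_batch(np.zeros((2, 7, 57)))


class TestLoss:
    def test_symmetric_prediction_gives_ln2(self):
        p = np.array([[0.5, 0.5]])
        assert cross_entropy(p, [0]) == pytest.approx(math.log(2))
        assert cross_entropy(p, [1]) == pytest.approx(math.log(2))

    def test_perfect_prediction_approaches_zero(self):
        assert cross_entropy(np.array([[1e-9, 1 - 1e-9]]), [1]) == pytest.approx(0.0, abs=1e-8)

    def test_direct_evaluation(self):
        assert cross_entropy(np.array([[0.2, 0.8]]), [1]) == pytest.approx(-math.log(0.8))

    def test_log_zero_guarded(self):
        assert np.isfinite(cross_entropy(np.array([[0.0, 1.0]]), [0]))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        m = BiLstmClassifier(_cfg(seed=7, precision="double"))
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3, 7, 7))
        y = np.array([1, 0, 1])
        probs, cache = m.forward_batch(X, with_cache=True)
        grads = m.backward_batch(probs, y, cache)

        def loss():
            return cross_entropy(m.forward_batch(X), y)

        for p, g in zip(m._param_list(), grads):
            num = np.zeros_like(g)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                eps, orig = 1e-6, p[i]
                p[i] = orig + eps
                lp = loss()
                p[i] = orig - eps
                lm = loss()
                p[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            rel = np.linalg.norm(num - g) / (np.linalg.norm(num) + np.linalg.norm(g) + 1e-30)
            assert rel < 1e-4


def _separable_windows(n, w=7, shift=6.0, seed=0):
    rng = np.random.default_rng(seed)
    Xn = rng.normal(0, 1, (n, w, 7)).astype(np.float32)
    Xp = rng.normal(0, 1, (n, w, 7)).astype(np.float32)
    Xp[:, w // 2, 0] += shift
    return Xp, Xn


class TestTraining:
    def test_separable_data_reaches_high_heldout_accuracy(self):
        Xp, Xn = _separable_windows(800, seed=1)
        m = BiLstmClassifier(_cfg(seed=2, hidden_size=8, batch_size=64,
                                  chunk_size=256, learning_rate=3e-3))
        hist = m.train(Xp[:600], Xn[:600], max_steps=150)
        assert all(np.isfinite(h["loss"]) for h in hist)
        assert hist[-1]["loss"] < hist[0]["loss"]
        p_pos = m.predict_proba(Xp[600:])
        p_neg = m.predict_proba(Xn[600:])
        acc = 0.5 * ((p_pos >= 0.5).mean() + (p_neg < 0.5).mean())
        assert acc >= 0.95

    def test_permuted_labels_stay_near_chance(self):
        # identically distributed classes: labels carry no information
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (800, 7, 7)).astype(np.float32)
        m = BiLstmClassifier(_cfg(seed=5, hidden_size=8, batch_size=64,
                                  chunk_size=256))
        m.train(X[:400], X[400:], max_steps=80)
        Xh = rng.normal(0, 1, (2, 400, 7, 7)).astype(np.float32)
        acc = 0.5 * ((m.predict_proba(Xh[0]) >= 0.5).mean()
                     + (m.predict_proba(Xh[1]) < 0.5).mean())
        assert abs(acc - 0.5) < 0.1

    def test_single_class_input_rejected(self):
        Xp, _ = _separable_windows(10)
        m = BiLstmClassifier(_cfg(seed=0))
        with pytest.raises(ValueError, match="both classes"):
            m.train(Xp, Xp[:0])

    def test_training_reproducible_given_seed(self):
        Xp, Xn = _separable_windows(200, seed=7)
        outs = []
        for _ in range(2):
            m = BiLstmClassifier(_cfg(seed=11, hidden_size=4, batch_size=32,
                                      chunk_size=64))
            m.train(Xp, Xn, max_steps=20)
            outs.append(m.predict_proba(Xp[:20]))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        m = BiLstmClassifier(_cfg(seed=13))
        path = tmp_path / "model.npz"
        m.save(path)
        back = BiLstmClassifier.load(path)
        X = np.random.default_rng(1).normal(size=(3, 7, 7))
        np.testing.assert_array_equal(m.forward_batch(X), back.forward_batch(X))
        assert back.config == m.config


class TestSplits:
    def test_read_split_fractions_disjoint_union(self):
        reads = [f"r{i}" for i in range(100)]
        train, test = split_read_based(reads, fraction=0.9, seed=0)
        assert len(train) == 90 and len(test) == 10
        assert set(train) | set(test) == set(reads)
        assert not set(train) & set(test)

    def test_read_split_honors_fraction_per_class(self):
        reads = [f"p{i}" for i in range(40)] + [f"n{i}" for i in range(20)]
        classes = ["pos"] * 40 + ["neg"] * 20
        train, test = split_read_based(reads, 0.9, seed=1, classes=classes)
        assert sum(r.startswith("p") for r in train) == 36
        assert sum(r.startswith("n") for r in train) == 18

    def test_read_split_seed_stability(self):
        reads = list(range(50))
        assert split_read_based(reads, seed=5) == split_read_based(reads, seed=5)

    def _window_set(self, positions):
        n = len(positions)
        return WindowSet(
            np.zeros((n, 3, 7), np.float32), np.zeros(n, np.int8),
            np.full(n, "c1", object), np.array(positions),
            np.full(n, "+"), np.full(n, "r", object),
        )

    def test_region_split_membership(self):
        ws = self._window_set(list(range(0, 500, 10)))
        train, test = split_region_based(ws, "c1", 100, 200)
        assert sorted(test.pos.tolist()) == list(range(100, 200, 10))
        assert not set(train.pos.tolist()) & set(test.pos.tolist())

    def test_empty_region_gives_empty_test(self):
        ws = self._window_set([1, 2, 3])
        _, test = split_region_based(ws, "c1", 500, 600)
        assert len(test) == 0

    def test_five_fold_region_rotation_covers_each_site_once(self):
        ws = self._window_set(list(range(0, 1000, 7)))
        folds = [(i * 200, (i + 1) * 200) for i in range(5)]
        seen = []
        for lo, hi in folds:
            _, test = split_region_based(ws, "c1", lo, hi)
            seen += test.pos.tolist()
        assert sorted(seen) == sorted(ws.pos.tolist())
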