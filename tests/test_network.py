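"""LSTM unit, bidirectional layers, stacked network forward pass, and model
serialization — checked against an independent fully-unrolled scalar oracle."""

import math

import numpy as np
import pytest

import phenolstm as pl
from phenolstm.network import LSTMParams, ModelFormatError, lstm_forward_batch


def make_params(rng, hidden, inp):
    arrs = {}
    for n in ("W_c", "W_i", "W_f", "W_o"):
        arrs[n] = rng.normal(size=(hidden, inp))
    for n in ("U_c", "U_i", "U_f", "U_o"):
        arrs[n] = rng.normal(size=(hidden, hidden))
    for n in ("b_c", "b_i", "b_f", "b_o"):
        arrs[n] = rng.normal(size=hidden)
    return LSTMParams(**arrs)


# --------------------------------------------------------------------------
# independent oracle: pure-python unrolled LSTM on nested lists


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))


def scalar_lstm_sequence(xs, p: LSTMParams):
    """Fully-unrolled per-element evaluation of the gate recurrences."""
    H = p.hidden_size
    h = [0.0] * H
    c = [0.0] * H
    out = []
    for x in xs:  # x is a list of input values
        def gate(W, U, b, fn):
            return [
                fn(sum(W[r][j] * x[j] for j in range(len(x)))
                   + sum(U[r][j] * h[j] for j in range(H)) + b[r])
                for r in range(H)
            ]

        ct = gate(p.W_c.tolist(), p.U_c.tolist(), p.b_c.tolist(), math.tanh)
        i = gate(p.W_i.tolist(), p.U_i.tolist(), p.b_i.tolist(), _sig)
        f = gate(p.W_f.tolist(), p.U_f.tolist(), p.b_f.tolist(), _sig)
        c = [i[r] * ct[r] + f[r] * c[r] for r in range(H)]
        o = gate(p.W_o.tolist(), p.U_o.tolist(), p.b_o.tolist(), _sig)
        h = [o[r] * math.tanh(c[r]) for r in range(H)]
        out.append(h)
    return out


class TestLstmStep:
    def test_zero_parameters_give_zero_state(self):
        p = LSTMParams(**{n: np.zeros((2, 3)) for n in ("W_c", "W_i", "W_f", "W_o")},
                       **{n: np.zeros((2, 2)) for n in ("U_c", "U_i", "U_f", "U_o")},
                       **{n: np.zeros(2) for n in ("b_c", "b_i", "b_f", "b_o")})
        h, c = pl.lstm_step(np.ones(3), np.zeros(2), np.zeros(2), p)
        assert (h == 0).all() and (c == 0).all()

    def test_scalar_unit_hand_evaluation(self):
        # all weights 1, biases 0, x=1, zero state: every pre-activation is 1
        p = LSTMParams(**{n: np.ones((1, 1)) for n in ("W_c", "W_i", "W_f", "W_o")},
                       **{n: np.ones((1, 1)) for n in ("U_c", "U_i", "U_f", "U_o")},
                       **{n: np.zeros(1) for n in ("b_c", "b_i", "b_f", "b_o")})
        h, c = pl.lstm_step(np.ones(1), np.zeros(1), np.zeros(1), p)
        sig1, tanh1 = 1 / (1 + math.exp(-1)), math.tanh(1)
        assert c[0] == pytest.approx(sig1 * tanh1, abs=1e-12)       # ~0.55677
        assert h[0] == pytest.approx(sig1 * math.tanh(sig1 * tanh1), abs=1e-12)  # ~0.36944

    def test_pure_memory_limit(self):
        # forget gate saturated open, input gate saturated shut: c_t -> c_prev
        p = LSTMParams(**{n: np.zeros((2, 2)) for n in ("W_c", "W_i", "W_f", "W_o")},
                       **{n: np.zeros((2, 2)) for n in ("U_c", "U_i", "U_f", "U_o")},
                       b_c=np.zeros(2), b_i=np.full(2, -50.0),
                       b_f=np.full(2, 50.0), b_o=np.zeros(2))
        c_prev = np.array([0.3, -0.7])
        _, c = pl.lstm_step(np.ones(2), np.zeros(2), c_prev, p)
        assert np.allclose(c, c_prev, atol=1e-12)

    def test_shape_mismatch_names_operand(self):
        p = make_params(np.random.default_rng(0), 2, 3)
        with pytest.raises(ValueError, match="x_t"):
            pl.lstm_step(np.ones(4), np.zeros(2), np.zeros(2), p)
        with pytest.raises(ValueError, match="h_prev"):
            pl.lstm_step(np.ones(3), np.zeros(3), np.zeros(2), p)

    def test_gate_ranges_for_random_parameters(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = make_params(rng, 3, 2)
            h, c = pl.lstm_step(rng.normal(size=2) * 5, rng.normal(size=3),
                                rng.normal(size=3), p)
            assert (np.abs(h) < 1).all()
            assert np.isfinite(c).all()


class TestBilstmLayer:
    def test_matches_stepwise_iteration(self):
        rng = np.random.default_rng(3)
        fwd, bwd = make_params(rng, 2, 1), make_params(rng, 2, 1)
        seq = rng.normal(size=(3, 1))
        out = pl.bilstm_layer(seq, fwd, bwd)
        # forward half by explicit stepping
        h = np.zeros(2); c = np.zeros(2)
        for t in range(3):
            h, c = pl.lstm_step(seq[t], h, c, fwd)
            if t == 2:
                assert np.allclose(out[2, :2], h, atol=1e-12)
        # backward half: reversed iteration re-reversed
        h = np.zeros(2); c = np.zeros(2)
        for t in (2, 1, 0):
            h, c = pl.lstm_step(seq[t], h, c, bwd)
        assert np.allclose(out[0, 2:], h, atol=1e-12)

    def test_palindromic_sequence_with_shared_params_is_symmetric(self):
        rng = np.random.default_rng(4)
        p = make_params(rng, 3, 2)
        seq = rng.normal(size=(5, 2))
        seq = np.concatenate([seq, seq[::-1][1:]])  # palindrome, T=9
        out = pl.bilstm_layer(seq, p, p)
        T = len(seq)
        for t in range(T):
            swapped = np.concatenate([out[T - 1 - t, 3:], out[T - 1 - t, :3]])
            assert np.allclose(out[t], swapped, atol=1e-12)

    def test_single_timestep_uses_zero_initial_states(self):
        rng = np.random.default_rng(6)
        fwd, bwd = make_params(rng, 2, 3), make_params(rng, 2, 3)
        x = rng.normal(size=(1, 3))
        out = pl.bilstm_layer(x, fwd, bwd)
        hf, _ = pl.lstm_step(x[0], np.zeros(2), np.zeros(2), fwd)
        hb, _ = pl.lstm_step(x[0], np.zeros(2), np.zeros(2), bwd)
        assert np.allclose(out[0], np.concatenate([hf, hb]), atol=1e-15)

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(0)
        fwd, bwd = make_params(rng, 2, 3), make_params(rng, 2, 3)
        with pytest.raises(ValueError):
            pl.bilstm_layer(np.empty((0, 3)), fwd, bwd)


class TestNetworkForward:
    def test_probabilities_sum_to_one(self):
        model = pl.init_network(4, 5, n_layers=2, hidden_size=6, seed=1)
        X = np.random.default_rng(2).normal(size=(7, 10, 4))
        ts, hidden, seq = pl.network_forward(model, X)
        assert np.abs(ts.sum(axis=2) - 1).max() < 1e-9
        assert np.abs(seq.sum(axis=1) - 1).max() < 1e-9
        assert (ts > 0).all() and (ts < 1).all()
        assert hidden.shape == (7, 10, 12)
        assert (np.abs(hidden) < 1).all()

    def test_eval_mode_is_deterministic(self):
        model = pl.init_network(3, 2, hidden_size=4, seed=0)
        X = np.random.default_rng(1).normal(size=(2, 6, 3))
        a = pl.network_forward(model, X, mode="eval")
        b = pl.network_forward(model, X, mode="eval")
        for x, y in zip(a, b):
            assert (x == y).all()

    def test_zero_head_gives_uniform_probabilities(self):
        model = pl.init_network(3, 4, hidden_size=4, seed=0)
        model.head_W[:] = 0.0
        model.head_b[:] = 0.0
        X = np.random.default_rng(1).normal(size=(2, 6, 3))
        ts, _, seq = pl.network_forward(model, X)
        assert np.allclose(ts, 0.25, atol=1e-12)
        assert np.allclose(seq, 0.25, atol=1e-12)

    def test_one_layer_network_equals_bilstm_plus_head(self):
        model = pl.init_network(3, 2, n_layers=1, hidden_size=4, seed=9)
        X = np.random.default_rng(3).normal(size=(1, 5, 3))
        _, hidden, seq = pl.network_forward(model, X)
        out = pl.bilstm_layer(X[0], *model.layers[0])
        assert np.allclose(hidden[0], out, atol=1e-15)
        repr_ = np.concatenate([out[-1, :4], out[0, 4:]])
        logits = model.head_W @ repr_ + model.head_b
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        assert np.allclose(seq[0], probs, atol=1e-12)

    def test_matches_unrolled_scalar_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            fwd, bwd = make_params(rng, 2, 3), make_params(rng, 2, 3)
            X = rng.normal(size=(4, 3))
            ours = pl.bilstm_layer(X, fwd, bwd)
            oracle_f = scalar_lstm_sequence(X.tolist(), fwd)
            oracle_b = scalar_lstm_sequence(X[::-1].tolist(), bwd)[::-1]
            oracle = np.concatenate([np.array(oracle_f), np.array(oracle_b)], axis=1)
            assert np.abs(ours - oracle).max() < 1e-12

    def test_train_mode_requires_rng_and_dropout_averages_to_eval(self):
        model = pl.init_network(5, 3, n_layers=2, hidden_size=6,
                                dropout_rate=0.5, seed=3)
        X = np.random.default_rng(1).normal(size=(4, 8, 5))
        with pytest.raises(ValueError, match="rng"):
            pl.network_forward(model, X, mode="train")
        _, _, ev = pl.network_forward(model, X, mode="eval")
        rng = np.random.default_rng(9)
        acc = np.zeros_like(ev)
        n_draws = 300
        for _ in range(n_draws):
            _, _, p = pl.network_forward(model, X, mode="train", rng=rng)
            acc += p
        # inverted dropout keeps the layer outputs unbiased, so the averaged
        # train-mode probabilities approach the eval-mode ones
        assert np.abs(acc / n_draws - ev).max() < 0.02

    def test_feature_count_mismatch_rejected(self):
        model = pl.init_network(4, 2, hidden_size=3, seed=0)
        with pytest.raises(ValueError, match="features"):
            pl.network_forward(model, np.zeros((1, 5, 6)))


class TestModelSerialization:
    def test_round_trip_preserves_outputs_and_metadata(self, tmp_path):
        model = pl.init_network(4, 3, n_layers=2, hidden_size=5,
                                class_names=["a", "b", "c"], n_timesteps=7, seed=2)
        path = tmp_path / "model.npz"
        pl.save_model(model, path)
        loaded = pl.load_model(path)
        X = np.random.default_rng(0).normal(size=(3, 7, 4))
        a = pl.network_forward(model, X)
        b = pl.network_forward(loaded, X)
        for x, y in zip(a, b):
            assert (x == y).all()
        assert loaded.n_layers == 2
        assert loaded.hidden_size == 5
        assert loaded.class_names == ["a", "b", "c"]

    def test_truncated_file_raises_format_error(self, tmp_path):
        model = pl.init_network(3, 2, hidden_size=4, seed=1)
        path = tmp_path / "model.npz"
        pl.save_model(model, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ModelFormatError):
            pl.load_model(path)

    def test_non_model_file_rejected(self, tmp_path):
        path = tmp_path / "other.npz"
        np.savez(path, x=np.ones(3))
        with pytest.raises(ModelFormatError, match="not a network model"):
            pl.load_model(path)


def test_batched_forward_matches_single_sequence():
    rng = np.random.default_rng(8)
    p = make_params(rng, 3, 2)
    X = rng.normal(size=(5, 6, 2))
    batched = lstm_forward_batch(X, p)
    for s in range(5):
        single = lstm_forward_batch(X[s:s + 1], p)
        assert np.allclose(batched[s], single[0], atol=1e-14)
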