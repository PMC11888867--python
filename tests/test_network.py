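import numpy as np
import pytest

from _oracles import softmax_attention_oracle
from amylstm import (
    AttentionParams, LSTMCellParams, LSTMCellState, ModelConfig,
    ProteinRecord, SequenceClassifier, attention_pool, build_model,
    reference_lstm_step, tokenize,
)
from amylstm.io_tokenize import TokenizedBatch
from amylstm.network import Adam, ConfigError, ShapeError, \
    lstm_cell_params_from_layer

HID, IN = 3, 4


def _zero_cell_params(hid=HID, inp=IN):
    W = np.zeros((hid, hid + inp))
    b = np.zeros(hid)
    return LSTMCellParams(W, W.copy(), W.copy(), W.copy(),
                          b, b.copy(), b.copy(), b.copy())


def _random_batch(rng, vocab=21, B=4, L=9):
    lengths = rng.integers(1, L + 1, size=B)
    lengths[0] = L
    mask = np.arange(L)[None, :] < lengths[:, None]
    idx = np.where(mask, rng.integers(1, vocab, size=(B, L)), 0)
    return TokenizedBatch(indices=idx, lengths=lengths, mask=mask)


class TestReferenceLSTMStep:
    def test_all_zero_weights_and_state(self):
        state = reference_lstm_step(
            _zero_cell_params(),
            LSTMCellState(C=np.zeros(HID), h=np.zeros(HID)),
            np.zeros(IN))
        np.testing.assert_allclose(state.C, 0.0)
        np.testing.assert_allclose(state.h, 0.0)

    def test_zero_weights_nonzero_cell(self):
        # gates are all 0.5, candidate 0: C' = C/2, h' = 0.5*tanh(C/2)
        c = np.array([1.0, -2.0, 0.5])
        state = reference_lstm_step(
            _zero_cell_params(),
            LSTMCellState(C=c, h=np.zeros(HID)), np.zeros(IN))
        np.testing.assert_allclose(state.C, 0.5 * c)
        np.testing.assert_allclose(state.h, 0.5 * np.tanh(0.5 * c))

    def test_hidden_state_bounded(self, rng):
        params = LSTMCellParams(
            *(rng.standard_normal((HID, HID + IN)) for _ in range(4)),
            *(rng.standard_normal(HID) for _ in range(4)))
        state = LSTMCellState(C=rng.standard_normal(HID),
                              h=np.tanh(rng.standard_normal(HID)))
        for _ in range(5):
            state = reference_lstm_step(params, state,
                                        rng.standard_normal(IN))
        assert (np.abs(state.h) < 1).all()

    def test_dimension_mismatch_names_operand(self):
        with pytest.raises(ShapeError, match="x has shape"):
            reference_lstm_step(
                _zero_cell_params(),
                LSTMCellState(C=np.zeros(HID), h=np.zeros(HID)),
                np.zeros(IN + 2))

    def test_trajectory_matches_vectorized_layer(self, rng):
        """Scalar reference cell composed over time equals the layer."""
        config = ModelConfig(vocab_size=10, embed_dim=6,
                             hidden_per_direction=5, fc_hidden=4,
                             bidirectional=False, seed=11, dtype="float64")
        model = build_model(config)
        batch = _random_batch(rng, vocab=10, B=1, L=12)
        X = model.params["embedding"][batch.indices]
        Hs, h_final, _ = model._run_direction(X, batch.mask, "fwd")
        cell = lstm_cell_params_from_layer(
            model.params["W_fwd"], model.params["b_fwd"])
        state = LSTMCellState(C=np.zeros(5), h=np.zeros(5))
        for t in range(12):
            state = reference_lstm_step(cell, state, X[0, t])
            np.testing.assert_allclose(Hs[0, t], state.h, atol=1e-4)
        np.testing.assert_allclose(h_final[0], state.h, atol=1e-4)


class TestAttentionPool:
    def _params(self, rng, d):
        return AttentionParams(W_k=rng.standard_normal((d, d)),
                               b_k=rng.standard_normal(d),
                               u_s=rng.standard_normal(d))

    def test_single_position_gets_weight_one(self, rng):
        H = rng.standard_normal((1, 6))
        V, alpha = attention_pool(H, self._params(rng, 6))
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(V, H[0])

    def test_identical_states_uniform_weights(self, rng):
        h = rng.standard_normal(6)
        H = np.tile(h, (5, 1))
        V, alpha = attention_pool(H, self._params(rng, 6))
        np.testing.assert_allclose(alpha, 0.2)
        np.testing.assert_allclose(V, h)

    def test_matches_masked_softmax_oracle(self, rng):
        params = self._params(rng, 6)
        H = rng.standard_normal((7, 6))
        mask = np.array([1, 1, 0, 1, 1, 0, 1], dtype=bool)
        V, alpha = attention_pool(H, params, mask)
        V_exp, alpha_exp = softmax_attention_oracle(
            H.tolist(), params.W_k.tolist(), params.b_k.tolist(),
            params.u_s.tolist(), mask.tolist())
        np.testing.assert_allclose(alpha, alpha_exp, atol=1e-6)
        np.testing.assert_allclose(V, V_exp, atol=1e-6)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)
        assert (alpha[~mask] == 0).all()

    def test_all_masked_raises(self, rng):
        with pytest.raises(ValueError, match="mask"):
            attention_pool(np.ones((3, 2)), self._params(rng, 2),
                           np.zeros(3, dtype=bool))


class TestModelAssembly:
    def test_default_pooled_width_is_128(self):
        config = ModelConfig()
        assert config.vocab_size == 21
        assert config.embed_dim == 100
        assert config.pooled_dim == 128

    def test_unknown_cell_raises(self):
        with pytest.raises(ConfigError, match="cell"):
            ModelConfig(cell="transformer")

    @pytest.mark.parametrize("cell", ["rnn", "gru", "lstm"])
    @pytest.mark.parametrize("attention", [True, False])
    def test_forward_yields_probabilities(self, rng, cell, attention):
        config = ModelConfig(cell=cell, attention=attention, embed_dim=8,
                             hidden_per_direction=6, fc_hidden=5, seed=2)
        model = build_model(config)
        batch = _random_batch(rng)
        p = model.predict_proba(batch)
        assert p.shape == (4,)
        assert ((p > 0) & (p < 1)).all()

    def test_length_one_sequence(self):
        model = build_model(ModelConfig(embed_dim=8, hidden_per_direction=4,
                                        fc_hidden=4, seed=0))
        batch = tokenize([ProteinRecord("a", "M")])
        p = model.predict_proba(batch)
        assert np.isfinite(p).all()

    def test_model_attention_matches_pool_function(self, rng):
        """The batched attention path equals the per-sequence formula."""
        config = ModelConfig(embed_dim=8, hidden_per_direction=6,
                             fc_hidden=5, seed=4, dtype="float64")
        model = build_model(config)
        batch = _random_batch(rng)
        _, alpha, cache = model._forward(batch.indices, batch.mask,
                                         training=False)
        params = AttentionParams(W_k=model.params["att_W"].T,
                                 b_k=model.params["att_b"],
                                 u_s=model.params["att_u"])
        for i in range(len(batch)):
            V_i, alpha_i = attention_pool(cache["Hcat"][i], params,
                                          batch.mask[i])
            np.testing.assert_allclose(alpha[i], alpha_i, atol=1e-6)
            np.testing.assert_allclose(cache["V"][i], V_i, atol=1e-6)


class TestPredictProba:
    def test_deterministic_in_eval_mode(self, rng):
        model = build_model(ModelConfig(embed_dim=8, hidden_per_direction=6,
                                        fc_hidden=5, seed=5))
        batch = _random_batch(rng)
        np.testing.assert_array_equal(model.predict_proba(batch),
                                      model.predict_proba(batch))

    def test_out_of_vocabulary_index_raises(self, rng):
        model = build_model(ModelConfig(vocab_size=21, embed_dim=8,
                                        hidden_per_direction=4, fc_hidden=4))
        batch = _random_batch(rng)
        batch.indices[0, 0] = 21
        with pytest.raises(ValueError, match="vocab"):
            model.predict_proba(batch)

    @pytest.mark.parametrize("attention", [True, False])
    def test_padding_invariance(self, rng, attention):
        """Extra pad columns change neither predictions nor attention."""
        model = build_model(ModelConfig(embed_dim=8, hidden_per_direction=6,
                                        fc_hidden=5, attention=attention,
                                        seed=6))
        batch = _random_batch(rng)
        p1 = model.predict_proba(batch)
        B, L = batch.indices.shape
        padded = TokenizedBatch(
            indices=np.concatenate(
                [batch.indices, np.zeros((B, 5), dtype=np.int64)], axis=1),
            lengths=batch.lengths,
            mask=np.concatenate(
                [batch.mask, np.zeros((B, 5), dtype=bool)], axis=1))
        p2 = model.predict_proba(padded)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        if attention:
            a1 = model.attention_weights(batch)
            a2 = model.attention_weights(padded)
            np.testing.assert_allclose(a1, a2[:, :L], atol=1e-6)
            assert (a2[:, L:] == 0).all()

    def test_attention_weights_are_distribution(self, rng):
        model = build_model(ModelConfig(embed_dim=8, hidden_per_direction=6,
                                        fc_hidden=5, seed=8))
        batch = _random_batch(rng)
        alpha = model.attention_weights(batch)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-5)
        assert (alpha[~batch.mask] == 0).all()
        assert (alpha >= 0).all()


class TestGradients:
    @pytest.mark.parametrize("cell", ["rnn", "gru", "lstm"])
    @pytest.mark.parametrize("attention", [True, False])
    def test_analytic_gradients_match_numerical(self, cell, attention):
        """Full backprop agrees with central finite differences."""
        config = ModelConfig(vocab_size=6, embed_dim=4, cell=cell,
                             attention=attention, hidden_per_direction=3,
                             fc_hidden=3, seed=3, dtype="float64")
        model = build_model(config)
        g = np.random.default_rng(0)
        idx = g.integers(1, 6, size=(4, 7))
        lengths = np.array([7, 5, 3, 6])
        mask = np.arange(7)[None, :] < lengths[:, None]
        batch = TokenizedBatch(indices=np.where(mask, idx, 0),
                               lengths=lengths, mask=mask)
        y = np.array([1.0, 0.0, 1.0, 0.0])
        _, grads = model.loss_and_grads(batch, y, update_bn_stats=False)
        eps = 1e-6
        for name, P in model.params.items():
            num = np.zeros_like(P)
            it = np.nditer(P, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                if name == "embedding" and i[0] == 0:
                    continue  # frozen pad row
                orig = P[i]
                P[i] = orig + eps
                lp = model.loss(batch, y, training=True)
                P[i] = orig - eps
                lm = model.loss(batch, y, training=True)
                P[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(grads[name], num, rtol=1e-4,
                                       atol=1e-7, err_msg=name)

    def test_single_example_loss_decreases_after_one_step(self):
        config = ModelConfig(embed_dim=8, hidden_per_direction=6,
                             fc_hidden=5, seed=9, dtype="float64")
        model = build_model(config)
        batch = tokenize([ProteinRecord("a", "QNNQQNYACD", label=1),
                          ProteinRecord("b", "GGSSTTRRKK", label=0)])
        y = np.array([1.0, 0.0])
        loss0, grads = model.loss_and_grads(batch, y)
        opt = Adam(model.params, lr=1e-3)
        opt.step(model.params, grads)
        loss1 = model.loss(batch, y, training=True)
        assert loss1 < loss0

    def test_training_batch_of_one_is_rejected(self):
        model = build_model(ModelConfig(embed_dim=8, hidden_per_direction=4,
                                        fc_hidden=4))
        batch = tokenize([ProteinRecord("a", "MKV", label=1)])
        with pytest.raises(ConfigError, match="batch"):
            model.loss_and_grads(batch, np.array([1.0]))


class TestPersistence:
    def test_save_load_roundtrip(self, rng, tmp_path):
        model = build_model(ModelConfig(embed_dim=8, hidden_per_direction=6,
                                        fc_hidden=5, seed=10))
        batch = _random_batch(rng)
        path = tmp_path / "model.npz"
        model.save(path)
        restored = SequenceClassifier.load(path)
        assert restored.config == model.config
        np.testing.assert_array_equal(model.predict_proba(batch),
                                      restored.predict_proba(batch))
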