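"""Architecture contract, reference operations, forward-pass behaviour."""

import numpy as np
import pytest

import somnostage as ss
import somnostage.nn as nn
from somnostage.model import epochs_to_input


def brute_force_trace(cfg):
    """Independent recomputation of the layer dimension rules."""
    dims = {}
    length = cfg.input_len
    for i, (f, k) in enumerate(cfg.conv_specs, start=1):
        length = length - k + 1
        dims[f"conv{i}"] = (length, f)
        length = length // cfg.pool_size
        dims[f"pool{i}"] = (length, f)
    dims["flatten"] = (length * cfg.conv_specs[-1][0],)
    dims["concatenate"] = (dims["flatten"][0] + cfg.lstm_units,)
    for i, s in enumerate(cfg.fc_sizes, start=1):
        dims[f"fc{i}"] = (s,)
    dims["softmax"] = (cfg.n_classes,)
    return dims


class TestShapeTrace:
    def test_canonical_dimension_list(self):
        trace = dict(ss.shape_trace(ss.ModelConfig()))
        assert trace["input"] == (300, 2)
        assert trace["lstm1"] == (300, 64)
        assert trace["lstm2"] == (64,)
        assert trace["conv1"] == (296, 64)
        assert trace["pool1"] == (98, 64)
        assert trace["conv2"] == (94, 32)
        assert trace["pool2"] == (31, 32)
        assert trace["flatten"] == (992,)
        assert trace["concatenate"] == (1056,)
        assert trace["fc1"] == (64,)
        assert trace["fc2"] == (32,)
        assert trace["softmax"] == (5,)

    def test_boundary_single_window(self):
        cfg = ss.ModelConfig(input_len=5, conv_specs=((4, 5),), pool_size=1,
                             fc_sizes=(3,))
        assert ss.shape_trace(cfg).shape_of("conv1") == (1, 4)

    def test_random_configs_match_brute_force(self):
        gen = np.random.default_rng(17)
        for _ in range(25):
            cfg = ss.ModelConfig(
                input_len=int(gen.integers(40, 400)),
                input_channels=int(gen.integers(1, 4)),
                lstm_units=int(gen.integers(4, 64)),
                lstm_layers=int(gen.integers(1, 3)),
                conv_specs=tuple(
                    (int(gen.integers(4, 32)), int(gen.integers(2, 6)))
                    for _ in range(int(gen.integers(1, 3)))
                ),
                pool_size=int(gen.integers(1, 4)),
                fc_sizes=tuple(int(gen.integers(4, 64))
                               for _ in range(int(gen.integers(1, 3)))),
            )
            try:
                trace = dict(ss.shape_trace(cfg))
            except ValueError:
                continue  # degenerate geometry is allowed to be rejected
            for name, shape in brute_force_trace(cfg).items():
                assert trace[name] == shape, name

    def test_collapsed_length_names_offending_layer(self):
        cfg = ss.ModelConfig(input_len=10, conv_specs=((4, 5), (4, 5)),
                             pool_size=3)
        with pytest.raises(ValueError, match="conv2|pool"):
            ss.shape_trace(cfg)


class TestConv1dValid:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(20, 3))
        kernels = np.zeros((1, 3, 3))
        for c in range(3):
            kernels[0, c, c] = 1.0
        np.testing.assert_allclose(nn.conv1d_valid(x, kernels), x)

    def test_hand_computed_sliding_sum(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        kernels = np.ones((2, 1, 1))
        out = nn.conv1d_valid(x, kernels)
        np.testing.assert_allclose(out[:, 0], [3.0, 5.0, 7.0])

    def test_matches_triple_loop(self, rng):
        L, C, K, F = 12, 3, 4, 5
        x = rng.normal(size=(L, C))
        kernels = rng.normal(size=(K, C, F))
        bias = rng.normal(size=F)
        out = nn.conv1d_valid(x, kernels, bias)
        expected = np.zeros((L - K + 1, F))
        for t in range(L - K + 1):
            for f in range(F):
                acc = bias[f]
                for m in range(K):
                    for c in range(C):
                        acc += x[t + m, c] * kernels[m, c, f]
                expected[t, f] = acc
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-12)

    def test_oversized_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            nn.conv1d_valid(rng.normal(size=(3, 1)),
                            rng.normal(size=(5, 1, 1)))


def random_cell_params(rng, units, in_dim):
    def m(*shape):
        return rng.normal(scale=0.5, size=shape)
    return nn.LSTMCellParams(
        W_f=m(units, in_dim), W_i=m(units, in_dim), W_o=m(units, in_dim),
        W_c=m(units, in_dim), U_f=m(units, units), U_i=m(units, units),
        U_o=m(units, units), U_c=m(units, units), b_f=m(units), b_i=m(units),
        b_o=m(units), b_c=m(units),
    )


class TestLSTMCellStep:
    def test_zero_parameters_closed_form(self):
        units = 4
        zeros = lambda *s: np.zeros(s)
        params = nn.LSTMCellParams(
            W_f=zeros(units, 2), W_i=zeros(units, 2), W_o=zeros(units, 2),
            W_c=zeros(units, 2), U_f=zeros(units, units),
            U_i=zeros(units, units), U_o=zeros(units, units),
            U_c=zeros(units, units), b_f=zeros(units), b_i=zeros(units),
            b_o=zeros(units), b_c=zeros(units),
        )
        v = np.array([0.5, -1.0, 2.0, 0.0])
        h, c = nn.lstm_cell_step(params, np.zeros(2), np.zeros(units), v)
        np.testing.assert_allclose(c, 0.5 * v, rtol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * v), rtol=1e-12)

    def test_matches_scalar_evaluation(self, rng):
        units, in_dim = 3, 2
        params = random_cell_params(rng, units, in_dim)
        x = rng.normal(size=in_dim)
        h_prev = rng.normal(size=units)
        c_prev = rng.normal(size=units)
        h, c = nn.lstm_cell_step(params, x, h_prev, c_prev)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        for u in range(units):
            f = sig(params.W_f[u] @ x + params.U_f[u] @ h_prev + params.b_f[u])
            i = sig(params.W_i[u] @ x + params.U_i[u] @ h_prev + params.b_i[u])
            ct = np.tanh(params.W_c[u] @ x + params.U_c[u] @ h_prev
                         + params.b_c[u])
            o = sig(params.W_o[u] @ x + params.U_o[u] @ h_prev + params.b_o[u])
            cu = f * c_prev[u] + i * ct
            assert abs(c[u] - cu) < 1e-10
            assert abs(h[u] - o * np.tanh(cu)) < 1e-10

    def test_saturated_gates_preserve_memory(self, rng):
        units = 3
        params = random_cell_params(rng, units, 2)
        params.b_f[:] = 50.0   # forget gate ~1
        params.b_i[:] = -50.0  # input gate ~0
        c_prev = rng.normal(size=units)
        _, c = nn.lstm_cell_step(params, rng.normal(size=2),
                                 rng.normal(size=units), c_prev)
        np.testing.assert_allclose(c, c_prev, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        params = random_cell_params(rng, 3, 2)
        with pytest.raises(ValueError):
            nn.lstm_cell_step(params, np.zeros(5), np.zeros(3), np.zeros(3))


class TestAttentionPool:
    def test_singleton_sequence_passthrough(self, rng):
        h = rng.normal(size=(1, 6))
        out = nn.attention_pool(h, np.array([3.2]))
        np.testing.assert_allclose(out, h[0])

    def test_uniform_scores_average(self, rng):
        h = rng.normal(size=(2, 4))
        out = nn.attention_pool(h, np.array([1.0, 1.0]))
        np.testing.assert_allclose(out, h.mean(axis=0), rtol=1e-12)

    def test_matches_brute_force(self, rng):
        h = rng.normal(size=(7, 5))
        scores = rng.normal(size=7)
        w = np.exp(scores - scores.max())
        w /= w.sum()
        expected = sum(w[i] * h[i] for i in range(7))
        np.testing.assert_allclose(nn.attention_pool(h, scores), expected,
                                   rtol=1e-12)


class TestFusedLSTMAgreesWithCell:
    def test_layer_equals_stepwise_reference(self):
        """Dual route: the batched fused layer must replay the per-gate
        reference recurrence."""
        rng = np.random.default_rng(0)
        layer = nn.LSTMLayer(3, 4, rng)
        x = np.random.default_rng(1).normal(0, 0.5, (2, 7, 3)).astype(np.float32)
        H = layer.forward(x)
        if H.shape[0] != 2:  # time-major output
            H = H.transpose(1, 0, 2)
        W, Ur, b = (layer.params[k].astype(np.float64) for k in ("W", "U", "b"))
        U = 4
        blocks = {g: k for k, g in enumerate("ifog")}

        def gate(mat, g):
            return mat[:, blocks[g] * U:(blocks[g] + 1) * U].T

        params = nn.LSTMCellParams(
            W_f=gate(W, "f"), W_i=gate(W, "i"), W_o=gate(W, "o"),
            W_c=gate(W, "g"), U_f=gate(Ur, "f"), U_i=gate(Ur, "i"),
            U_o=gate(Ur, "o"), U_c=gate(Ur, "g"),
            b_f=b[U:2 * U], b_i=b[:U], b_o=b[2 * U:3 * U], b_c=b[3 * U:],
        )
        for bidx in range(2):
            h = np.zeros(U)
            c = np.zeros(U)
            for t in range(7):
                h, c = nn.lstm_cell_step(params, x[bidx, t].astype(np.float64),
                                         h, c)
                np.testing.assert_allclose(H[bidx, t], h, atol=1e-5)


class TestStagerModel:
    def test_realized_shapes_equal_trace(self, small_config):
        model = ss.build_model(small_config, seed=0)
        x = np.random.default_rng(0).normal(0, 50, (3, 30, 2))
        model.forward(x)
        assert model.last_shapes == [(n, tuple(s)) for n, s in model.trace]

    def test_softmax_rows_are_probabilities(self, small_config):
        model = ss.build_model(small_config, seed=0)
        x = np.random.default_rng(1).normal(0, 50, (6, 30, 2))
        probs = model.predict_proba(x)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_parameters(self, small_config):
        a = ss.build_model(small_config, seed=7)
        b = ss.build_model(small_config, seed=7)
        for (la, na), (lb, nb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(la.params[na], lb.params[nb])

    def test_untrained_model_scores_uniformly(self, small_config):
        model = ss.build_model(small_config, seed=0)
        x = np.random.default_rng(2).normal(0, 50, (4, 30, 2))
        probs = model.predict_proba(x)
        assert np.all((probs >= 0.1) & (probs <= 0.3))

    def test_batch_permutation_equivariance(self, small_config):
        model = ss.build_model(small_config, seed=0)
        x = np.random.default_rng(3).normal(0, 50, (5, 30, 2))
        perm = np.array([4, 2, 0, 3, 1])
        probs = model.predict_proba(x)
        probs_perm = model.predict_proba(x[perm])
        np.testing.assert_allclose(probs[perm], probs_perm, atol=1e-6)

    def test_attention_pool_variant_runs(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, use_attention_pool=True)
        model = ss.build_model(cfg, seed=0)
        x = np.random.default_rng(4).normal(0, 50, (3, 30, 2))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestPredict:
    def _records(self, n, fs=10.0):
        gen = np.random.default_rng(5)
        return [
            ss.EpochRecord(
                samples=gen.normal(0, 50, (int(fs * 30), 2)), fs_hz=fs,
                stage=ss.StageLabel.W, subject_id="S01", night_id="S01_n1",
                epoch_index=i,
            )
            for i in range(n)
        ]

    def test_labels_consistent_with_probabilities(self, small_config):
        model = ss.build_model(small_config, seed=1)
        records = self._records(6)
        labels, probs = ss.predict(model, records)
        assert [int(l) for l in labels] == list(np.argmax(probs, axis=1))

    def test_inference_is_repeatable(self, small_config):
        model = ss.build_model(small_config, seed=1)
        records = self._records(4)
        _, p1 = ss.predict(model, records)
        _, p2 = ss.predict(model, records)
        np.testing.assert_array_equal(p1, p2)

    def test_higher_rate_epochs_are_decimated(self, small_config):
        model = ss.build_model(small_config, seed=1)
        records = self._records(2, fs=100.0)
        x = epochs_to_input(records, small_config)
        assert x.shape == (2, 30, 2)

    def test_channel_mismatch_names_epoch(self, small_config):
        model = ss.build_model(small_config, seed=1)
        bad = ss.EpochRecord(
            samples=np.zeros((300, 3)), fs_hz=10.0, stage=ss.StageLabel.W,
            subject_id="S", night_id="n", epoch_index=0,
        )
        with pytest.raises(ValueError, match="epoch 0"):
            ss.predict(model, [bad])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, small_config, tmp_path):
        model = ss.build_model(small_config, seed=3)
        x = np.random.default_rng(6).normal(0, 50, (4, 30, 2))
        before = model.predict_proba(x)
        path = tmp_path / "model.npz"
        ss.save_checkpoint(model, path)
        restored = ss.load_checkpoint(path)
        np.testing.assert_allclose(restored.predict_proba(x), before,
                                   atol=1e-7)
        assert restored.config == model.config
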