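"""Network architecture, gradients, training loop and feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdcnn_ecg import synthetic_ecg as se
from rdcnn_ecg.denoise import znormalize_beat
from rdcnn_ecg.rdcnn import (
    DegenerateLabelsError,
    DenseBlock,
    ModelConfigError,
    RDCNNConfig,
    ResidualBlock,
    TrainConfig,
    build_model,
    count_parameters,
    dense_block_forward,
    extract_features,
    load_model,
    residual_block_forward,
    save_model,
    train_model,
)
from rdcnn_ecg.rdcnn.layers import cross_entropy
from rdcnn_ecg.rdcnn.training import predict_classes

TINY = RDCNNConfig(
    num_res_blocks=1, num_dense_blocks=1, num_res_layers=1, num_dense_layers=1,
    filters=8, head_units=12, dropout_rate=0.0,
)


def _zero_branch(block: ResidualBlock) -> None:
    for conv, bn, relu in block.layers:
        conv.params["W"][:] = 0.0
        conv.params["b"][:] = 0.0


class TestArchitecture:
    def test_blockless_parameter_count(self):
        # stem 1*63*3+63, head 63*64+64, output 64*5+5
        config = RDCNNConfig(num_res_blocks=0, num_dense_blocks=0)
        model = build_model(config, 187, seed=0)
        total, breakdown = count_parameters(model)
        assert total == 4_673
        assert breakdown == {"stem": 252, "head": 4_096, "out": 325}

    def test_head_doubling_formula(self):
        c1 = RDCNNConfig(num_res_blocks=0, num_dense_blocks=0, head_units=64)
        c2 = RDCNNConfig(num_res_blocks=0, num_dense_blocks=0, head_units=128)
        _, b1 = count_parameters(build_model(c1, 187, 0))
        _, b2 = count_parameters(build_model(c2, 187, 0))
        # head contribution doubles; output layer gains 64 weights per class
        assert b2["head"] == 2 * b1["head"]  # 63*128+128 == 2*(63*64+64)
        assert b2["out"] - b1["out"] == 64 * 5

    def test_softmax_outputs_form_simplex(self):
        model = build_model(TINY, 64, seed=1)
        probs = model.predict_proba(np.random.default_rng(0).standard_normal((7, 64)))
        assert probs.shape == (7, 5)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_weights(self):
        w1 = build_model(TINY, 64, seed=3).get_weights()
        w2 = build_model(TINY, 64, seed=3).get_weights()
        assert all(np.array_equal(w1[k], w2[k]) for k in w1)

    def test_pooling_below_one_sample_rejected(self):
        config = RDCNNConfig(num_res_blocks=8, num_dense_blocks=8,
                             num_res_layers=1, num_dense_layers=1, filters=4)
        with pytest.raises(ModelConfigError):
            build_model(config, 32, seed=0)


class TestResidualBlock:
    def test_zero_weights_give_identity(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(8, 2, 8, 3, rng)
        _zero_branch(block)
        x = rng.standard_normal((3, 32, 8))
        np.testing.assert_array_equal(residual_block_forward(x, block), x)

    def test_shape_preserved(self):
        block = ResidualBlock(63, 2, 63, 3, np.random.default_rng(1))
        x = np.random.default_rng(2).standard_normal((2, 187, 63))
        assert residual_block_forward(x, block).shape == (2, 187, 63)

    def test_identity_kernel_doubles_nonnegative_input(self):
        # single layer, center-tap identity convolution, inert batch norm:
        # F(x) = x so the block returns x + x = 2x for x >= 0
        block = ResidualBlock(4, 1, 4, 3, np.random.default_rng(0))
        conv, bn, _ = block.layers[0]
        conv.params["W"][:] = 0.0
        conv.params["b"][:] = 0.0
        conv.params["W"][np.arange(4) + 4, np.arange(4)] = 1.0  # center tap
        x = np.abs(np.random.default_rng(3).standard_normal((2, 16, 4)))
        out = residual_block_forward(x, block)  # inference: running stats 0/1
        np.testing.assert_allclose(out, 2.0 * x, rtol=1e-4)

    def test_projection_handles_channel_mismatch(self):
        block = ResidualBlock(12, 1, 8, 3, np.random.default_rng(4))
        x = np.random.default_rng(5).standard_normal((2, 20, 12))
        assert residual_block_forward(x, block).shape == (2, 20, 8)


class TestDenseBlock:
    def test_channel_growth(self):
        block = DenseBlock(63, 2, 63, 3, np.random.default_rng(0))
        assert block.out_channels == 189
        x = np.random.default_rng(1).standard_normal((1, 32, 63))
        assert dense_block_forward(x, block).shape == (1, 32, 189)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        c_in=st.integers(1, 16),
        n_layers=st.integers(1, 4),
        filters=st.integers(1, 16),
    )
    def test_channel_growth_formula_randomized(self, c_in, n_layers, filters):
        block = DenseBlock(c_in, n_layers, filters, 3, np.random.default_rng(0))
        assert block.out_channels == c_in + n_layers * filters
        x = np.random.default_rng(1).standard_normal((1, 8, c_in))
        assert dense_block_forward(x, block).shape[2] == c_in + n_layers * filters

    def test_zero_weights_pass_input_through(self):
        block = DenseBlock(5, 1, 3, 3, np.random.default_rng(0))
        conv, bn, _ = block.layers[0]
        conv.params["W"][:] = 0.0
        conv.params["b"][:] = 0.0
        x = np.random.default_rng(2).standard_normal((2, 16, 5))
        out = dense_block_forward(x, block)
        np.testing.assert_array_equal(out[..., :5], x)
        np.testing.assert_array_equal(out[..., 5:], 0.0)

    def test_matches_brute_force_convolution(self):
        # 1 layer over an 8-sample, 2-channel input, checked against a
        # direct loop computation of same-padded convolution + concat
        rng = np.random.default_rng(7)
        block = DenseBlock(2, 1, 3, 3, rng)
        conv, bn, _ = block.layers[0]
        x = rng.standard_normal((1, 8, 2))
        out = dense_block_forward(x, block)
        w = conv.params["W"].reshape(3, 2, 3)  # (tap, c_in, c_out)
        xp = np.pad(x[0], ((1, 1), (0, 0)))
        expected = np.zeros((8, 3))
        for pos in range(8):
            for tap in range(3):
                expected[pos] += xp[pos + tap] @ w[tap]
        expected += conv.params["b"]
        # inert batch norm at inference (running stats 0/1), then ReLU
        expected = np.maximum(expected / np.sqrt(1 + bn.eps), 0.0)
        np.testing.assert_allclose(out[0, :, 2:], expected, rtol=1e-6)
        np.testing.assert_array_equal(out[0, :, :2], x[0])

    def test_last_only_variant_growth(self):
        block = DenseBlock(6, 3, 4, 3, np.random.default_rng(0),
                           connectivity="last-only")
        x = np.random.default_rng(1).standard_normal((1, 16, 6))
        assert dense_block_forward(x, block).shape[2] == 10


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        config = RDCNNConfig(
            num_res_blocks=1, num_dense_blocks=1, num_res_layers=1,
            num_dense_layers=2, filters=4, head_units=6, dropout_rate=0.0,
            n_classes=3,
        )
        model = build_model(config, 32, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 32))
        y = rng.integers(0, 3, 5)

        logits = model.forward(x, training=True)
        _, glogits = cross_entropy(logits, y)
        model.backward(glogits)

        eps = 1e-6
        for name, layer in model.named_layers():
            for key, param in layer.params.items():
                idx = tuple(rng.integers(0, s) for s in param.shape)
                orig = param[idx]
                param[idx] = orig + eps
                lp, _ = cross_entropy(model.forward(x, training=True), y)
                param[idx] = orig - eps
                lm, _ = cross_entropy(model.forward(x, training=True), y)
                param[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = layer.grads[key][idx]
                assert abs(numeric - analytic) <= 1e-4 * max(
                    1.0, abs(numeric) + abs(analytic)
                ), f"{name}.{key}"


class TestTraining:
    def test_overfits_separable_beats(self):
        beats, labels, _ = se.generate_dataset(
            {c: 10 for c in range(5)}, 187, None, seed=0
        )
        beats = np.vstack([znormalize_beat(b) for b in beats])
        config = RDCNNConfig(
            num_res_blocks=1, num_dense_blocks=1, num_res_layers=1,
            num_dense_layers=1, filters=32, head_units=32, dropout_rate=0.0,
        )
        model = build_model(config, 187, seed=0)
        train_model(
            model, beats, labels,
            TrainConfig(max_epochs=50, patience=50, batch_size=10,
                        learning_rate=0.005, validation_fraction=0.0, seed=0),
        )
        accuracy = (predict_classes(model, beats) == labels).mean()
        assert accuracy >= 0.95

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        beats, labels, _ = se.generate_dataset({0: 8, 1: 8}, 64, None, seed=1)
        model = build_model(TINY, 64, seed=0)
        before = model.get_weights()
        train_model(
            model, beats, labels,
            TrainConfig(learning_rate=0.0, max_epochs=1, patience=1, seed=0),
        )
        after = model.get_weights()
        for key in before:
            if "running_" in key:  # batch-norm statistics still update
                continue
            assert np.abs(before[key] - after[key]).max() < 1e-9, key

    def test_early_stopping_halts_on_plateau(self):
        # a blockless model has no batch-norm state, so lr=0 freezes the
        # validation loss exactly: the first epoch is the best and
        # training must stop patience epochs later
        blockless = RDCNNConfig(
            num_res_blocks=0, num_dense_blocks=0, filters=8, head_units=8,
            dropout_rate=0.0,
        )
        beats, labels, _ = se.generate_dataset({0: 20, 1: 20}, 64, None, seed=2)
        model = build_model(blockless, 64, seed=0)
        train_model(
            model, beats, labels,
            TrainConfig(learning_rate=0.0, max_epochs=20, patience=3,
                        validation_fraction=0.2, seed=0),
        )
        epochs_run = len(model.history["val_loss"])
        assert epochs_run <= 3 + 1

    def test_history_lengths_match_epochs_run(self):
        beats, labels, _ = se.generate_dataset({0: 10, 1: 10}, 64, None, seed=3)
        model = build_model(TINY, 64, seed=0)
        train_model(model, beats, labels,
                    TrainConfig(max_epochs=3, patience=3, seed=0))
        lengths = {len(v) for v in model.history.values()}
        assert lengths == {3}

    def test_single_class_rejected(self):
        beats, labels, _ = se.generate_dataset({2: 10}, 64, None, seed=0)
        model = build_model(TINY, 64, seed=0)
        with pytest.raises(DegenerateLabelsError):
            train_model(model, beats, labels, TrainConfig())

    def test_validation_loss_not_worse_than_init(self):
        beats, labels, _ = se.generate_dataset(
            {c: 16 for c in range(5)}, 187, None, seed=4
        )
        beats = np.vstack([znormalize_beat(b) for b in beats])
        config = RDCNNConfig(
            num_res_blocks=1, num_dense_blocks=1, num_res_layers=1,
            num_dense_layers=1, filters=16, head_units=16, dropout_rate=0.0,
        )
        model = build_model(config, 187, seed=0)
        train_model(model, beats, labels,
                    TrainConfig(max_epochs=10, patience=10, seed=0))
        assert min(model.history["val_loss"]) <= model.history["val_loss"][0]


class TestFeatures:
    def test_shape_nonnegativity_and_determinism(self):
        model = build_model(TINY, 64, seed=2)
        beats = np.random.default_rng(0).standard_normal((10, 64))
        feats = extract_features(model, beats)
        assert feats.shape == (10, TINY.head_units)
        assert np.all(feats >= 0)  # rectified head
        np.testing.assert_array_equal(extract_features(model, beats), feats)

    def test_identical_rows_identical_features(self):
        model = build_model(TINY, 64, seed=2)
        row = np.random.default_rng(1).standard_normal(64)
        feats = extract_features(model, np.stack([row, row]))
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_length_mismatch_rejected(self):
        model = build_model(TINY, 64, seed=2)
        with pytest.raises(ValueError):
            extract_features(model, np.zeros((2, 100)))

    def test_parameter_count_invariant_under_training(self):
        beats, labels, _ = se.generate_dataset({0: 8, 1: 8}, 64, None, seed=5)
        model = build_model(TINY, 64, seed=0)
        before, _ = count_parameters(model)
        train_model(model, beats, labels,
                    TrainConfig(max_epochs=2, patience=2, seed=0))
        after, _ = count_parameters(model)
        assert before == after

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(TINY, 64, seed=6)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        beats = np.random.default_rng(2).standard_normal((4, 64))
        np.testing.assert_allclose(
            extract_features(loaded, beats), extract_features(model, beats)
        )
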