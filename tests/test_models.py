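"""Architecture and training-protocol contracts: layer shapes, parameter
counts, numeric gradients, determinism, permutation invariance,
serialization."""

import numpy as np
import pytest

from sweepnet import nn
from sweepnet.models import (
    SpecError,
    TrainConfig,
    TrainingError,
    build_deepset,
    build_imagene,
    build_mini_cnn,
    build_network,
    extract_mini_cnn_weights,
    load_model,
    predict,
    save_model,
    train,
)


def toy_dataset(rng, n=64, h=16, w=16):
    """Separable images: sweep class has identical top-half rows."""
    x = (rng.random((n, h, w)) < 0.5).astype(np.float32)
    y = np.zeros(n, dtype=np.float32)
    y[n // 2 :] = 1
    for i in range(n // 2, n):
        x[i, : h // 2] = x[i, 0]  # copy one row across the top half
    order = rng.permutation(n)
    return x[order], y[order]


class TestArchitectures:
    def test_mini_cnn_parameter_count(self):
        spec = build_mini_cnn(128, 128)
        net = build_network(spec, np.random.default_rng(0))
        # kernel 2 + bias 1 + dense 127*128 + dense bias 1
        assert net.param_count() == 3 + 127 * 128 + 1 == 16_260

    def test_mini_cnn_difference_detector(self):
        spec = build_mini_cnn(4, 3)
        net = build_network(spec, np.random.default_rng(0))
        weights = net.get_weights()
        weights[0] = np.array([[1.0], [-1.0]], dtype=np.float32)  # (w, -w)
        weights[1][:] = 0
        net.set_weights(weights)
        x = np.tile((np.arange(3) % 2).astype(np.float32), (4, 1))[None]
        conv = net.layers[0].forward(x[..., None])
        assert np.allclose(conv, 0)  # identical consecutive rows

    def test_mini_cnn_variants_distinct(self):
        assert build_mini_cnn(8, 8).layers != build_mini_cnn(8, 8, kernel=(1, 2)).layers
        assert len(build_mini_cnn(8, 8, relu=False).layers) == 4
        with pytest.raises(SpecError):
            build_mini_cnn(1, 8)

    def test_imagene_shapes_and_param_count(self):
        spec = build_imagene(128, 128)
        net = build_network(spec, np.random.default_rng(0))
        # hand sum over layers: conv 3x3x1x32, conv 3x3x32x32 (x2), dense
        conv1 = 3 * 3 * 1 * 32 + 32
        conv2 = 3 * 3 * 32 * 32 + 32
        conv3 = conv2
        # 128 -conv-> 126 -pool-> 63 -conv-> 61 -pool-> 30 -conv-> 28 -pool-> 14
        dense1 = 14 * 14 * 32 * 64 + 64
        dense2 = 64 + 1
        assert net.param_count() == conv1 + conv2 + conv3 + dense1 + dense2
        with pytest.raises(SpecError):
            build_imagene(8, 8)  # too small for three pooling stages

    def test_deepset_param_count_height_independent(self):
        n64 = build_network(build_deepset(64, 64), np.random.default_rng(0)).param_count()
        n128 = build_network(build_deepset(128, 64), np.random.default_rng(0)).param_count()
        assert n64 == n128
        with pytest.raises(SpecError):
            build_deepset(16, 8)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for spec in (build_mini_cnn(12, 20), build_imagene(32, 32), build_deepset(8, 16)):
            net = build_network(spec, rng)
            out = net.predict(rng.random((4, *spec.input_shape)).astype(np.float32))
            assert ((out >= 0) & (out <= 1)).all()


class TestGradients:
    def test_backprop_matches_numeric_gradients(self):
        net = nn.Network(
            [
                nn.Conv2D(3, (2, 2), init="glorot_uniform"),
                nn.ReLU(),
                nn.MaxPool2x2(),
                nn.Conv2D(2, (1, 3), init="glorot_uniform"),
                nn.ReLU(),
                nn.MeanOverRows(),
                nn.Flatten(),
                nn.Dense(4),
                nn.ReLU(),
                nn.Dense(1),
                nn.Sigmoid(),
            ],
            (8, 9, 1),
            l1=0.001,
            l2=0.002,
        )
        net.init_params(np.random.default_rng(1))
        rng = np.random.default_rng(2)
        x = rng.random((5, 8, 9, 1)).astype(np.float32)
        y = rng.integers(0, 2, 5).astype(np.float32)

        def loss():
            return nn.bce_loss(net.forward(x.copy()), y) + net.regularization_loss()

        p = net.forward(x.copy())
        g = ((p - y) / len(y)).astype(np.float32).reshape(-1, 1)
        for layer in reversed(net.layers[:-1]):
            g = layer.backward(g)
        for value, grad, reg in net.parameters():
            full = (grad + (0.001 * np.sign(value) + 0.004 * value if reg else 0)).copy()
            flat, gflat = value.reshape(-1), full.reshape(-1)
            for idx in rng.choice(flat.size, min(6, flat.size), replace=False):
                eps, orig = 1e-3, flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[idx], abs=2e-2 * max(1.0, abs(num)))


class TestTraining:
    def test_zero_learning_rate_keeps_weights(self):
        rng = np.random.default_rng(0)
        x, y = toy_dataset(rng)
        spec = build_mini_cnn(16, 16)
        cfg = TrainConfig(learning_rate=0.0, restarts=1, seed=7)
        model = train(spec, x[:48], y[:48], x[48:], y[48:], cfg)
        init_net = build_network(spec, np.random.default_rng(7))
        for got, want in zip(model.weights, init_net.get_weights()):
            assert np.array_equal(got, want)

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        x, y = toy_dataset(rng, n=128)
        spec = build_mini_cnn(16, 16)
        cfg = TrainConfig(restarts=3, epochs=60, seed=3)
        model = train(spec, x, y, x, y, cfg)
        net = model.network()
        acc = np.mean((net.predict(x) > 0.5).astype(int) == y)
        assert acc == 1.0

    def test_determinism_and_restart_selection(self):
        rng = np.random.default_rng(2)
        x, y = toy_dataset(rng)
        spec = build_mini_cnn(16, 16)
        cfg = TrainConfig(restarts=2, seed=11)
        a = train(spec, x[:48], y[:48], x[48:], y[48:], cfg)
        b = train(spec, x[:48], y[:48], x[48:], y[48:], cfg)
        assert a.restart_index == b.restart_index
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        assert len(a.history["restarts"]) == 2

    def test_loss_not_worse_than_initialization(self):
        rng = np.random.default_rng(3)
        x, y = toy_dataset(rng)
        spec = build_mini_cnn(16, 16)
        cfg = TrainConfig(restarts=1, seed=5)
        model = train(spec, x[:48], y[:48], x[48:], y[48:], cfg)
        init_net = build_network(spec, np.random.default_rng(5))
        trained_net = model.network()
        assert trained_net.evaluate_loss(x[:48], y[:48]) <= init_net.evaluate_loss(
            x[:48], y[:48]
        )

    def test_single_class_split_rejected(self):
        rng = np.random.default_rng(4)
        x, _ = toy_dataset(rng, n=16)
        with pytest.raises(TrainingError):
            train(
                build_mini_cnn(16, 16),
                x, np.zeros(16), x, np.zeros(16),
                TrainConfig(restarts=1),
            )


class TestPredictAndSerialize:
    def test_deepset_exact_permutation_invariance(self):
        rng = np.random.default_rng(0)
        spec = build_deepset(16, 24)
        net = build_network(spec, rng)
        from sweepnet.models import TrainedModel

        model = TrainedModel(spec=spec, weights=net.get_weights(),
                             val_accuracy=0.0, seed=0, restart_index=0)
        x = (rng.random((3, 16, 24)) < 0.5).astype(np.float32)
        base = predict(model, x)
        for _ in range(3):
            perm = rng.permutation(16)
            assert np.array_equal(predict(model, x[:, perm]), base)
        # duplicating every row leaves the row-mean unchanged
        doubled = np.repeat(x, 2, axis=1)
        spec2 = build_deepset(32, 24)
        model2 = TrainedModel(spec=spec2, weights=model.weights,
                              val_accuracy=0.0, seed=0, restart_index=0)
        assert np.allclose(predict(model2, doubled), base, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        spec = build_mini_cnn(8, 8)
        net = build_network(spec, rng)
        from sweepnet.models import TrainedModel

        model = TrainedModel(spec=spec, weights=net.get_weights(),
                             val_accuracy=0.0, seed=0, restart_index=0)
        with pytest.raises(TrainingError):
            predict(model, rng.random((2, 9, 8)))

    def test_round_trip_reproduces_scores(self, tmp_path):
        rng = np.random.default_rng(2)
        x, y = toy_dataset(rng, n=32)
        model = train(
            build_mini_cnn(16, 16), x[:24], y[:24], x[24:], y[24:],
            TrainConfig(restarts=1, seed=1),
        )
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.array_equal(predict(back, x), predict(model, x))
        assert back.spec == model.spec

    def test_extract_mini_cnn_weights(self):
        rng = np.random.default_rng(3)
        spec = build_mini_cnn(128, 128)
        net = build_network(spec, rng)
        from sweepnet.models import TrainedModel

        model = TrainedModel(spec=spec, weights=net.get_weights(),
                             val_accuracy=0.0, seed=0, restart_index=0)
        kernel, dense = extract_mini_cnn_weights(model)
        assert kernel.shape == (2, 1)
        assert dense.shape == (127, 128)
        # untrained weights equal the initializer draws for the seed
        ref = build_network(spec, np.random.default_rng(3))
        assert np.array_equal(kernel.reshape(-1), ref.get_weights()[0].reshape(-1))
        with pytest.raises(TypeError):
            extract_mini_cnn_weights(
                TrainedModel(spec=build_deepset(16, 16),
                             weights=[], val_accuracy=0, seed=0, restart_index=0)
            )
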