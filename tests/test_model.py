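"""Network building blocks, training behaviour, and prediction contracts."""

import numpy as np
import pytest

from vibroscrew import nn
from vibroscrew.excitation import ConfigurationError
from vibroscrew.model import (
    ModelConfig,
    build_model,
    classify,
    desk_scale_config,
    load_model,
    predict,
    predict_batch,
    save_model,
    se_block,
    train,
)


class TestLayerGradients:
    """Analytic backward passes against numerical differentiation."""

    @staticmethod
    def _input_grad_error(layer, x, eps=1e-2):
        rng = np.random.default_rng(99)
        w = rng.standard_normal(layer.forward(x.copy(), True).shape)

        def loss():
            return float(np.sum(layer.forward(x.copy(), True).astype(np.float64) * w))

        layer.forward(x.copy(), True)
        dx = layer.backward(w.astype(np.float32))
        gx = np.zeros_like(x, dtype=np.float64)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = x[ix]
            x[ix] = orig + eps
            lp = loss()
            x[ix] = orig - eps
            lm = loss()
            x[ix] = orig
            gx[ix] = (lp - lm) / (2 * eps)
        return np.linalg.norm(dx - gx) / np.linalg.norm(gx)

    @pytest.mark.parametrize(
        "layer_fn",
        [
            lambda rng: nn.Conv2d(4, 3, k=3, stride=1, rng=rng),
            lambda rng: nn.Conv2d(4, 3, k=3, stride=2, rng=rng),
            lambda rng: nn.Conv2d(4, 3, k=1, stride=2, rng=rng),
            lambda rng: nn.BatchNorm2d(4),
            lambda rng: nn.SEBlock(4, 2, rng=rng),
        ],
        ids=["conv-s1", "conv-s2", "conv-1x1", "batchnorm", "se"],
    )
    def test_backward_matches_numerical(self, layer_fn):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 6, 5, 4)).astype(np.float32)
        if isinstance(layer := layer_fn(rng), nn.SEBlock):
            x = np.abs(x)
        assert self._input_grad_error(layer, x) < 1e-3

    def test_conv_matches_scipy_correlate(self):
        from scipy.signal import correlate

        rng = np.random.default_rng(1)
        conv = nn.Conv2d(3, 5, k=3, stride=2, rng=rng)
        x = rng.standard_normal((2, 9, 8, 3)).astype(np.float32)
        y = conv.forward(x, train=False)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        for b in range(2):
            for o in range(5):
                full = sum(
                    correlate(xp[b, :, :, c], conv.w.data[:, :, c, o], mode="valid")
                    for c in range(3)
                )
                assert np.allclose(y[b, :, :, o], full[::2, ::2], atol=1e-5)

    def test_maxpool_routes_gradient_to_argmax(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 6, 7, 4)).astype(np.float32)
        mp = nn.MaxPool2x2()
        y = mp.forward(x, True)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx = mp.backward(dy)
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        expected = np.zeros_like(x)
        for b in range(n):
            for i in range(oh):
                for j in range(ow):
                    for ch in range(c):
                        win = x[b, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, ch]
                        ai, aj = np.unravel_index(win.argmax(), (2, 2))
                        expected[b, 2 * i + ai, 2 * j + aj, ch] += dy[b, i, j, ch]
        assert np.array_equal(dx, expected)


class TestSEBlock:
    def test_zero_input_maps_to_zero(self):
        out = se_block(np.zeros((2, 5, 4, 8), dtype=np.float32), r=8)
        assert np.array_equal(out, np.zeros_like(out))

    def test_gating_attenuates_nonnegative_inputs(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.standard_normal((2, 5, 4, 8))).astype(np.float32)
        out = se_block(x, r=2, rng=rng)
        assert np.max(np.abs(out), axis=(1, 2)).max() <= np.max(np.abs(x)) + 1e-6
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_reduction_gives_bottleneck_width(self):
        blk = nn.SEBlock(8, 8)
        assert blk.fc1.w.data.shape == (1, 8)  # C/r = 1

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            se_block(np.zeros((1, 2, 2, 6), dtype=np.float32), r=4)


class TestArchitecture:
    def test_eighteen_weighted_layers(self):
        assert build_model(ModelConfig()).weighted_layer_count == 18

    def test_forward_emits_probability_in_unit_interval(self):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24))
        net = build_model(cfg)
        p = predict(net, np.zeros((32, 24)))
        assert 0.0 <= p <= 1.0

    def test_forward_deterministic(self):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          rng_seed=4)
        net = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((32, 24))
        assert predict(net, x) == predict(net, x)

    def test_se_ablation_keeps_layer_count(self):
        net = build_model(ModelConfig(use_se=False))
        assert net.weighted_layer_count == 18
        assert all(blk.se is None for blk in net.blocks)

    def test_shape_mismatch_rejected(self):
        net = build_model(ModelConfig(stage_filter_counts=(8, 8, 8, 8),
                                      input_shape=(32, 24)))
        with pytest.raises(ValueError, match="spatial shape"):
            predict(net, np.zeros((16, 24)))

    def test_indivisible_se_reduction_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(stage_filter_counts=(12, 24, 48, 96), se_reduction=8)


def _toy_dataset(n=16, shape=(32, 24), seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n):
        v = 1.0 if i % 2 else -1.0
        data.append((np.full(shape, v) + 0.01 * rng.standard_normal(shape), i % 2))
    return data


class TestTraining:
    def test_fits_linearly_separable_toy_data(self):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          epochs=10, learning_rate=1e-3, batch_size=8, rng_seed=1)
        data = _toy_dataset()
        tm = train(build_model(cfg), data, cfg)
        probs = predict_batch(tm, [x for x, _ in data])
        acc = np.mean((probs > 0.5).astype(int) == np.array([y for _, y in data]))
        assert acc >= 0.95
        assert len(tm.loss_history) == 10

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigurationError, match="epochs"):
            ModelConfig(epochs=0)

    def test_single_class_training_set_rejected(self):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          epochs=1)
        data = [(np.zeros((32, 24)), 1), (np.ones((32, 24)), 1)]
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(cfg), data, cfg)

    def test_seeded_training_reproducible(self):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          epochs=2, learning_rate=1e-3, batch_size=8, rng_seed=7)
        data = _toy_dataset(n=8)
        l1 = train(build_model(cfg), data, cfg).loss_history
        l2 = train(build_model(cfg), data, cfg).loss_history
        assert np.allclose(l1, l2, rtol=1e-4)

    def test_single_step_decreases_single_example_loss(self):
        """One Adam update at the published learning rate reduces the loss of
        the example it was computed on."""
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          epochs=1, learning_rate=1e-5, rng_seed=3)
        net = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((1, 32, 24)).astype(np.float32)
        y = np.array([1.0])
        opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
        logits = net.forward(x, train=True)
        loss0, d = nn.bce_with_logits(logits, y)
        net.backward(d)
        opt.step()
        loss1, _ = nn.bce_with_logits(net.forward(x, train=True), y)
        assert loss1 < loss0


class TestPrediction:
    def test_threshold_boundary_is_fixed(self):
        assert classify(0.5) == "fixed"
        assert classify(0.9) == "loose"
        assert classify(0.0) == "fixed"

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            classify(1.5)

    def test_batch_matches_per_item(self):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          rng_seed=2)
        net = build_model(cfg)
        rng = np.random.default_rng(1)
        specs = [rng.standard_normal((32, 24)) for _ in range(5)]
        batched = predict_batch(net, specs)
        single = np.array([predict(net, s) for s in specs])
        assert np.allclose(batched, single, atol=1e-6)


class TestCheckpointing:
    def test_save_load_preserves_predictions(self, tmp_path):
        cfg = ModelConfig(stage_filter_counts=(8, 8, 8, 8), input_shape=(32, 24),
                          epochs=2, learning_rate=1e-3, batch_size=8, rng_seed=5)
        data = _toy_dataset(n=8)
        tm = train(build_model(cfg), data, cfg)
        path = save_model(tm, tmp_path / "model.npz")
        back = load_model(path)
        x = np.random.default_rng(9).standard_normal((32, 24))
        assert predict(back, x) == pytest.approx(predict(tm, x), abs=1e-7)
        assert back.loss_history == pytest.approx(tm.loss_history)
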