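import numpy as np
import pytest

from skullmark import nn
from skullmark.errors import ConfigError, InvalidInputError, ModelStateError
from skullmark.fcn import (BottleneckSpec, Bottleneck, FCNConfig, TrainConfig,
                           _epoch_loss, bottleneck_forward, build_fcn,
                           load_checkpoint, predict_landmarks, save_checkpoint,
                           train_fcn)
from skullmark.frames import CropWindow, LandmarkSet
from skullmark.heatmap import HeatmapConfig, make_label


class TestConfig:
    def test_net_size_must_allow_four_halvings(self):
        with pytest.raises(ConfigError):
            FCNConfig(net_size=100)

    def test_channel_schedule_must_double(self):
        with pytest.raises(ConfigError):
            FCNConfig(bottleneck_block_out_channels=(128, 200, 512))

    def test_default_reference_channels(self):
        cfg = FCNConfig()
        assert cfg.width(cfg.conv1_out_channels) == 32
        assert [cfg.width(c) for c in cfg.bottleneck_block_out_channels] == [128, 256, 512]

    def test_tiny_preset_quarter_width(self):
        cfg = FCNConfig.tiny()
        assert cfg.net_size == 64
        assert cfg.width(32) == 8 and cfg.width(128) == 32


class TestArchitecture:
    @pytest.mark.parametrize("n", [64, 128])
    def test_shape_contract_by_forward_trace(self, n, rng):
        model = build_fcn(FCNConfig(net_size=n, width_multiplier=0.25))
        x = rng.random((1, 3, n, n), dtype=np.float32)
        assert model.forward(x, train=False).shape == (1, 2, n, n)
        assert model.spatial_trace() == [n // 2, n // 4, n // 8, n // 16]

    def test_block_channel_trace(self, rng):
        model = build_fcn(FCNConfig(net_size=64, width_multiplier=1.0))
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        h = model.conv1.forward(x, train=False)
        assert h.shape[1] == 32
        sizes = []
        for block in model.blocks:
            h = block.forward(h, train=False)
            sizes.append(h.shape[1])
        assert sizes == [128, 256, 512]

    def test_parameter_count_deterministic(self):
        a = build_fcn(FCNConfig.tiny(seed=0))
        b = build_fcn(FCNConfig.tiny(seed=0))
        assert a.parameter_count() == b.parameter_count()
        assert all(np.array_equal(p.value, q.value)
                   for p, q in zip(a.params(), b.params()))

    def test_flip_equivariance_absent_by_default(self, rng):
        # randomly initialised weights must not hide a built-in symmetry
        model = build_fcn(FCNConfig.tiny(seed=3))
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        y = model.forward(x, train=False)
        y_flip = model.forward(x[:, :, :, ::-1].copy(), train=False)[:, :, :, ::-1]
        assert not np.allclose(y, y_flip, atol=1e-5)

    def test_bad_input_shape(self):
        model = build_fcn(FCNConfig.tiny())
        with pytest.raises(InvalidInputError):
            model.forward(np.zeros((1, 3, 32, 32), np.float32))


class TestBottleneck:
    def test_zero_weight_limit_is_relu_of_input(self, rng):
        spec = BottleneckSpec(n_in=6, n_out=6, stride=1)
        layer = Bottleneck(spec, rng)
        for p in layer.params():
            p.value[...] = 0.0
        layer.bn1.gamma.value[...] = 1.0  # BN identity in eval mode
        layer.bn2.gamma.value[...] = 1.0
        layer.bn3.gamma.value[...] = 1.0
        x = rng.standard_normal((2, 6, 8, 8)).astype(np.float32)
        y = layer.forward(x, train=False)
        assert np.allclose(y, np.maximum(x, 0.0), atol=1e-5)

    def test_stride_two_halves_spatial_size(self, rng):
        y = bottleneck_forward(np.zeros((1, 8, 16, 16), np.float32),
                               BottleneckSpec(8, 16, stride=2), rng)
        assert y.shape == (1, 16, 8, 8)

    def test_internal_channels_quarter_of_output(self):
        assert BottleneckSpec(32, 128).internal_channels == 32

    def test_identity_shortcut_rule(self):
        assert BottleneckSpec(64, 64, stride=1).identity_shortcut
        assert not BottleneckSpec(64, 64, stride=2).identity_shortcut
        assert not BottleneckSpec(32, 64, stride=1).identity_shortcut

    def test_channel_mismatch_rejected(self, rng):
        layer = Bottleneck(BottleneckSpec(8, 16), rng)
        with pytest.raises(InvalidInputError):
            layer.forward(np.zeros((1, 4, 8, 8), np.float32))


class TestTraining:
    def _toy_pairs(self, rng, n=16, size=64):
        # learnable toy task: every image carries the same label, so the
        # loop must at least fit the mean within a few epochs
        X = rng.random((n, 3, size, size), dtype=np.float32)
        lm = LandmarkSet((20.0, 20.0), (44.0, 44.0), frame="net")
        lab = make_label((size, size), lm, HeatmapConfig(sigma=5), frame="net")
        Y = np.repeat(np.moveaxis(lab.values, -1, 0)[None], n, axis=0)
        return X, Y.astype(np.float32)

    def test_zero_final_layer_gives_zero_loss_on_zero_labels(self, rng):
        model = build_fcn(FCNConfig.tiny(seed=0))
        final = model.conv2.layers[-1]
        final.W.value[...] = 0.0
        final.b.value[...] = 0.0
        X = rng.random((4, 3, 64, 64), dtype=np.float32)
        Y = np.zeros((4, 2, 64, 64), np.float32)
        assert _epoch_loss(model, X, Y, batch=4) == 0.0

    def test_loss_decreases_and_history_recorded(self, rng):
        # few-step smoke run: training-mode loss must fall; validation is
        # recorded per epoch (its improvement over a real schedule is
        # checked by the end-to-end protocol tests, where the batch-norm
        # running statistics have time to settle)
        X, Y = self._toy_pairs(rng)
        model, hist = train_fcn((X, Y), (X[:4], Y[:4]),
                                TrainConfig(epochs=6, seed=0))
        assert len(hist["train_loss"]) == 6 and len(hist["val_loss"]) == 6
        assert min(hist["train_loss"]) < hist["train_loss"][0]
        assert model.trained

    def test_same_seed_identical_histories(self, rng):
        X, Y = self._toy_pairs(rng, n=8)
        _, h1 = train_fcn((X, Y), (X[:2], Y[:2]), TrainConfig(epochs=2, seed=9))
        _, h2 = train_fcn((X, Y), (X[:2], Y[:2]), TrainConfig(epochs=2, seed=9))
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_size_mismatch_rejected(self, rng):
        X = rng.random((4, 3, 64, 64), dtype=np.float32)
        Y = np.zeros((4, 2, 32, 32), np.float32)
        with pytest.raises(InvalidInputError):
            train_fcn((X, Y), (X, Y), TrainConfig(epochs=1))


class _OracleModel:
    """Stub that returns a perfect label regardless of the image."""

    trained = True

    def __init__(self, label_values):
        self._out = np.moveaxis(label_values, -1, 0)[None]

    def forward(self, x, train=False):
        return np.repeat(self._out, len(x), axis=0)


class TestPrediction:
    def test_perfect_heatmap_decodes_to_truth_in_crop_frame(self):
        win = CropWindow(origin=(100, 200), crop_size=160, net_size=64)
        lm = LandmarkSet((20, 30), (44, 30), frame="net")
        lab = make_label((64, 64), lm, HeatmapConfig(sigma=5), frame="net")
        model = _OracleModel(lab.values)
        pred = predict_landmarks(model, np.zeros((64, 64, 3), np.float32), win)
        assert pred.frame == "crop"
        assert tuple(pred.bregma) == (50.0, 75.0)   # 20*2.5, 30*2.5
        assert tuple(pred.lambda_) == (110.0, 75.0)

    def test_upscale_first_agrees_within_scale_quantum(self):
        win = CropWindow(origin=(0, 0), crop_size=160, net_size=64)
        lm = LandmarkSet((20, 30), (44, 30), frame="net")
        lab = make_label((64, 64), lm, HeatmapConfig(sigma=5), frame="net")
        model = _OracleModel(lab.values)
        x = np.zeros((64, 64, 3), np.float32)
        a = predict_landmarks(model, x, win, upscale_first=False)
        b = predict_landmarks(model, x, win, upscale_first=True)
        assert np.abs(a.as_array() - b.as_array()).max() <= 2.5

    def test_constant_output_ties_to_origin(self):
        win = CropWindow(origin=(0, 0), crop_size=160, net_size=64)
        model = _OracleModel(np.full((64, 64, 2), 0.3, np.float32))
        pred = predict_landmarks(model, np.zeros((64, 64, 3), np.float32), win)
        assert tuple(pred.bregma) == (0.0, 0.0)

    def test_untrained_model_rejected(self):
        model = build_fcn(FCNConfig.tiny())
        win = CropWindow(origin=(0, 0), crop_size=160, net_size=64)
        with pytest.raises(ModelStateError):
            predict_landmarks(model, np.zeros((64, 64, 3), np.float32), win)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, rng):
        model = build_fcn(FCNConfig.tiny(seed=4))
        model.trained = True
        x = rng.random((2, 3, 64, 64), dtype=np.float32)
        model.forward(x, train=True)  # move BN stats
        y = model.forward(x, train=False)
        p = tmp_path / "model.npz"
        save_checkpoint(p, model, extra={"note": "test"})
        back, extra = load_checkpoint(p)
        assert extra == {"note": "test"}
        assert np.array_equal(back.forward(x, train=False), y)
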