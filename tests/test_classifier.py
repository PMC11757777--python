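"""Fusion-module algebra, head contracts and training-phase freezing."""

import numpy as np
import pytest

from oraltils import nn
from oraltils.nn.tensor import Tensor
from oraltils.classifier import (
    ClassifierConfig,
    ClsTrainConfig,
    FusionModule,
    ModalityClassifier,
    cross_entropy,
    inverse_frequency_weights,
    predict_proba,
    pretrain_encoder,
    train_fusion,
)


@pytest.fixture(scope="module")
def tiny_cls_cfg():
    return ClassifierConfig(input_size=32, encoder_variant="micro")


@pytest.fixture(scope="module")
def tiny_dataset(rng_module):
    """Three colour-separable classes of 32x32 tiles."""
    colors = [(200, 60, 60), (60, 200, 60), (60, 60, 200)]
    data = []
    for cls, col in enumerate(colors):
        for _ in range(8):
            img = np.full((32, 32, 3), col, np.uint8)
            img = np.clip(
                img.astype(int) + rng_module.integers(-20, 20, img.shape), 0, 255
            ).astype(np.uint8)
            data.append((img, cls))
    return data


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(7)


class TestFusionModule:
    def test_attention_weights_in_unit_interval(self, rng):
        fm = FusionModule(6, 4, out_ch=8)
        nn.init_parameters(fm, 0)
        fi = Tensor(rng.normal(size=(2, 6, 2, 2)).astype(np.float32) * 5)
        fc = Tensor(rng.normal(size=(2, 4, 2, 2)).astype(np.float32) * 5)
        att = fm.attention_weights(fi, fc).data
        assert att.shape == (2, 4, 1, 1)
        assert (att > 0).all() and (att < 1).all()

    def test_output_channels_fixed_at_projection_width(self, rng):
        fm = FusionModule(6, 4, out_ch=16)
        nn.init_parameters(fm, 0)
        fi = Tensor(rng.normal(size=(2, 6, 2, 2)).astype(np.float32))
        fc = Tensor(rng.normal(size=(2, 4, 2, 2)).astype(np.float32))
        out = fm(fi, fc)
        assert out.shape == (2, 16, 2, 2)  # spatial of fx_cell, 16 channels

    def test_zero_cell_features_collapse_to_bias_pattern(self, rng):
        fm = FusionModule(3, 3, out_ch=4)
        nn.init_parameters(fm, 1)
        fm.eval()  # running stats: BN acts affinely
        fi = Tensor(rng.normal(size=(1, 3, 2, 2)).astype(np.float32))
        fc = Tensor(np.zeros((1, 3, 2, 2), np.float32))
        pre = fm.project(fc * fm.attention_weights(fi, fc)).data
        assert np.allclose(pre, 0.0, atol=1e-6)  # projection has no bias

    def test_matches_hand_unrolled_scalar_computation(self):
        """1x1 spatial, 2-channel toy with pinned weights vs explicit algebra."""
        fm = FusionModule(2, 2, out_ch=2)
        nn.init_parameters(fm, 0)
        fm.align.weight.data = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1) * 2.0
        fm.align.bias.data = np.array([0.1, -0.1], np.float32)
        att_w = np.zeros((2, 2, 3, 3), np.float32)
        att_w[0, 0, 1, 1] = 1.0  # only the centre tap sees the 1x1 input
        att_w[1, 1, 1, 1] = -1.0
        fm.att.weight.data = att_w
        fm.att.bias.data = np.array([0.2, 0.3], np.float32)
        fx_img = np.array([0.5, -1.0], np.float32).reshape(1, 2, 1, 1)
        fx_cell = np.array([2.0, 4.0], np.float32).reshape(1, 2, 1, 1)
        got = fm.attention_weights(Tensor(fx_img), Tensor(fx_cell)).data.ravel()
        g_img = fx_img.ravel()  # GAP of a 1x1 map is the identity
        g_cell = 2.0 * fx_cell.ravel() + np.array([0.1, -0.1])
        g_join = g_img + g_cell
        expect = 1.0 / (1.0 + np.exp(-(np.array([1.0, -1.0]) * g_join + [0.2, 0.3])))
        np.testing.assert_allclose(got, expect, atol=1e-6)


class TestHeadAndLoss:
    def test_probabilities_sum_to_one(self, tiny_cls_cfg, rng):
        m = ModalityClassifier(tiny_cls_cfg)
        nn.init_parameters(m, 0)
        p = predict_proba(m, rng.integers(0, 255, (4, 32, 32, 3)).astype(np.uint8))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic_with_dropout_disabled(self, tiny_cls_cfg, rng):
        m = ModalityClassifier(tiny_cls_cfg)
        nn.init_parameters(m, 0)
        x = rng.integers(0, 255, (2, 32, 32, 3)).astype(np.uint8)
        np.testing.assert_array_equal(predict_proba(m, x), predict_proba(m, x))

    def test_cross_entropy_perfect_prediction_zero(self):
        probs = Tensor(np.array([[1.0, 0.0, 0.0]], np.float32))
        assert cross_entropy(probs, np.array([0])).item() < 1e-5

    def test_cross_entropy_half_confidence_ln2(self):
        probs = Tensor(np.array([[0.5, 0.5]], np.float32))
        assert cross_entropy(probs, np.array([1])).item() == pytest.approx(np.log(2), rel=1e-5)

    def test_cross_entropy_monotone_in_true_class_mass(self):
        lo = Tensor(np.array([[0.2, 0.4, 0.4]], np.float32))
        hi = Tensor(np.array([[0.6, 0.2, 0.2]], np.float32))
        y = np.array([0])
        assert cross_entropy(hi, y).item() < cross_entropy(lo, y).item()

    def test_label_order_round_trips(self, tiny_cls_cfg):
        for i, name in enumerate(tiny_cls_cfg.label_order):
            assert tiny_cls_cfg.label_to_index(name) == i
            assert tiny_cls_cfg.index_to_label(i) == name

    def test_inverse_frequency_weights_formula(self):
        labels = np.array([0] * 8 + [1] * 2 + [2] * 2)
        w = inverse_frequency_weights(labels, 3)
        assert w[0] == pytest.approx(12 / (3 * 8))
        assert w[1] == pytest.approx(12 / (3 * 2))


class TestTrainingPhases:
    def test_pretrained_image_classifier_beats_chance(self, tiny_cls_cfg, tiny_dataset):
        model, _ = pretrain_encoder(
            "image", tiny_dataset, tiny_cls_cfg,
            ClsTrainConfig(epochs=12, batch_size=8, seed=0), seed=0,
        )
        x = np.stack([a for a, _ in tiny_dataset])
        y = np.array([b for _, b in tiny_dataset])
        acc = (predict_proba(model, x).argmax(1) == y).mean()
        assert acc > 1 / 3

    def test_encoder_emits_spatial_feature_map(self, tiny_cls_cfg, rng):
        m = ModalityClassifier(tiny_cls_cfg)
        nn.init_parameters(m, 0)
        feats = m.features(Tensor(rng.random((1, 3, 32, 32)).astype(np.float32)))
        assert feats.ndim == 4  # (N, C, H, W), head removed

    def test_pretraining_reproducible_per_seed(self, tiny_cls_cfg, tiny_dataset):
        cfg = ClsTrainConfig(epochs=2, batch_size=8, seed=5)
        _, h1 = pretrain_encoder("image", tiny_dataset, tiny_cls_cfg, cfg, seed=5)
        _, h2 = pretrain_encoder("image", tiny_dataset, tiny_cls_cfg, cfg, seed=5)
        assert h1["train_loss"] == h2["train_loss"]

    def test_encoders_frozen_during_fusion_training(self, tiny_cls_cfg, tiny_dataset):
        cfg = ClsTrainConfig(epochs=2, batch_size=8, seed=0)
        img_m, _ = pretrain_encoder("image", tiny_dataset, tiny_cls_cfg, cfg, seed=1)
        cell_m, _ = pretrain_encoder("cell", tiny_dataset, tiny_cls_cfg, cfg, seed=2)
        paired = [(a, a[:, ::-1].copy(), y) for a, y in tiny_dataset]
        before = [p.data.copy() for p in img_m.encoder.parameters()] + [
            p.data.copy() for p in cell_m.encoder.parameters()
        ]
        fused, _ = train_fusion(img_m, cell_m, paired, tiny_cls_cfg, cfg, seed=3)
        after = [p.data for p in fused.phi_img.parameters()] + [
            p.data for p in fused.phi_cell.parameters()
        ]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_encoder_gradients_exactly_zero_when_frozen(self, tiny_cls_cfg, tiny_dataset, rng):
        cfg = ClsTrainConfig(epochs=1, batch_size=8, seed=0)
        img_m, _ = pretrain_encoder("image", tiny_dataset[:8], tiny_cls_cfg, cfg, seed=1)
        cell_m, _ = pretrain_encoder("cell", tiny_dataset[:8], tiny_cls_cfg, cfg, seed=2)
        paired = [(a, a, y) for a, y in tiny_dataset[:8]]
        fused, _ = train_fusion(img_m, cell_m, paired, tiny_cls_cfg, cfg, seed=3)
        # one explicit backward pass: frozen encoder weights get no gradient
        from oraltils.classifier import _nchw

        x = Tensor(_nchw(np.stack([a for a, _, _ in paired])))
        c = Tensor(_nchw(np.stack([b for _, b, _ in paired])))
        fused.zero_grad()
        loss = cross_entropy(fused(x, c), np.array([y for _, _, y in paired]))
        loss.backward()
        frozen = [p for p in fused.phi_img.parameters()] + list(fused.phi_cell.parameters())
        assert all(not p.trainable for p in frozen)
        live = [p for m in fused.trainable_modules() for p in m.parameters()]
        assert any(p.grad is not None and np.abs(p.grad).sum() > 0 for p in live)

    def test_unpaired_sizes_rejected(self, tiny_cls_cfg, tiny_dataset):
        img_m = ModalityClassifier(tiny_cls_cfg)
        cell_m = ModalityClassifier(tiny_cls_cfg)
        bad = [(np.zeros((32, 32, 3), np.uint8), np.zeros((16, 16, 3), np.uint8), 0)]
        with pytest.raises(ValueError, match="paired"):
            train_fusion(img_m, cell_m, bad, tiny_cls_cfg)


class TestClassWeighting:
    def test_weighting_raises_minority_recall_on_imbalanced_data(self, rng_module):
        """Inverse-frequency weighting balances recalls on a 10:1 skew."""
        colors = [(200, 60, 60), (60, 200, 60), (60, 60, 200)]
        data = []
        for cls, n in [(0, 30), (1, 3), (2, 3)]:
            for _ in range(n):
                img = np.full((32, 32, 3), colors[cls], np.uint8)
                img = np.clip(
                    img.astype(int) + rng_module.integers(-30, 30, img.shape), 0, 255
                ).astype(np.uint8)
                data.append((img, cls))
        cfg_w = ClassifierConfig(input_size=32, encoder_variant="micro")
        cfg_u = ClassifierConfig(
            input_size=32, encoder_variant="micro", class_weights={0: 1.0, 1: 1.0, 2: 1.0}
        )
        tcfg = ClsTrainConfig(epochs=6, batch_size=12, seed=4)
        paired = [(a, a, y) for a, y in data]
        img_m, _ = pretrain_encoder("image", data, cfg_w, tcfg, seed=4)
        cell_m, _ = pretrain_encoder("cell", data, cfg_w, tcfg, seed=5)

        def min_recall(cfg):
            fused, _ = train_fusion(img_m, cell_m, paired, cfg, tcfg, seed=6)
            x = np.stack([a for a, _, _ in paired])
            y = np.array([c for _, _, c in paired])
            pred = predict_proba(fused, x, x).argmax(1)
            recalls = [
                (pred[y == c] == c).mean() if (y == c).any() else 0.0 for c in range(3)
            ]
            return min(recalls)

        assert min_recall(cfg_w) >= min_recall(cfg_u)
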