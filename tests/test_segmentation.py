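"""Architecture contracts and loss-function oracles for the segmenter."""

import numpy as np
import pytest

from oraltils import nn
from oraltils.nn.tensor import Tensor
from oraltils.segmentation import (
    AttentionGate,
    LossConfig,
    SegModelConfig,
    SegTrainConfig,
    build_tilseg,
    dice_loss,
    focal_loss,
    mse_loss,
    one_hot,
    predict_tile,
    total_loss,
    train_segmentation,
)


class TestModelShapes:
    def test_output_matches_input_resolution_and_simplex(self, untrained_seg_model, rng):
        x = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
        probs, dist = untrained_seg_model(x)
        assert probs.shape == (2, 5, 64, 64)
        assert dist.shape == (2, 1, 64, 64)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-5)
        assert (dist.data > 0).all() and (dist.data < 1).all()

    def test_zero_input_probabilities_normalized(self, untrained_seg_model):
        probs, _ = untrained_seg_model(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-5)

    def test_parameter_count_reported(self):
        micro = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"))
        xs = build_tilseg(SegModelConfig(input_size=128, encoder_variant="xs"))
        assert 0 < micro.parameter_count() < xs.parameter_count()

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError, match="downsampling"):
            build_tilseg(SegModelConfig(input_size=100))

    def test_num_classes_fixed(self):
        with pytest.raises(ValueError):
            SegModelConfig(num_classes=4).validate()


class TestAttentionGate:
    def test_coefficients_in_open_unit_interval(self, rng):
        gate = AttentionGate(4, 6)
        nn.init_parameters(gate, 0)
        skip = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(2, 6, 8, 8)).astype(np.float32))
        coeff = gate.coefficients(skip, g).data
        assert (coeff > 0).all() and (coeff < 1).all()

    def test_zero_skip_gives_zero_output(self, rng):
        gate = AttentionGate(4, 6)
        nn.init_parameters(gate, 0)
        skip = Tensor(np.zeros((1, 4, 4, 4), np.float32))
        g = Tensor(np.zeros((1, 6, 4, 4), np.float32))
        assert (gate(skip, g).data == 0).all()

    def test_matches_hand_unrolled_scalar_computation(self):
        """2x2 single-channel toy with fixed weights against explicit algebra."""
        gate = AttentionGate(1, 1, inter_ch=1)
        gate.w_x.weight.data = np.full((1, 1, 1, 1), 2.0, np.float32)
        gate.w_g.weight.data = np.full((1, 1, 1, 1), -1.0, np.float32)
        gate.w_g.bias.data = np.array([0.5], np.float32)
        gate.psi.weight.data = np.full((1, 1, 1, 1), 1.5, np.float32)
        gate.psi.bias.data = np.array([-0.25], np.float32)
        skip = np.array([[1.0, 2.0], [0.5, -1.0]], np.float32)
        g = np.array([[0.0, 1.0], [2.0, 0.5]], np.float32)
        out = gate(Tensor(skip[None, None]), Tensor(g[None, None])).data[0, 0]
        pre = np.maximum(2.0 * skip + (-1.0 * g + 0.5), 0.0)
        psi = 1.0 / (1.0 + np.exp(-(1.5 * pre - 0.25)))
        np.testing.assert_allclose(out, skip * psi, atol=1e-6)


class TestLosses:
    def test_focal_perfect_prediction_vanishes(self):
        t = one_hot(np.array([[[1]]]), 5)
        probs = Tensor(t * 0.9999 + 1e-5)
        assert focal_loss(probs, t).item() < 1e-3

    def test_focal_closed_form_half_confidence(self):
        # single pixel, p_t = 0.5, gamma = 2, alpha = 0.25:
        # 0.25 * 0.25 * ln 2 = 0.043321...
        t = one_hot(np.array([[[0]]]), 5)
        p = np.full((1, 5, 1, 1), 0.125, np.float32)
        p[0, 0] = 0.5
        val = focal_loss(Tensor(p), t, gamma=2.0, alpha=0.25).item()
        assert val == pytest.approx(0.25 * 0.25 * np.log(2), rel=1e-4)

    def test_focal_degenerates_to_cross_entropy(self, rng):
        mask = rng.integers(0, 5, (1, 4, 4))
        t = one_hot(mask, 5)
        p = rng.dirichlet(np.ones(5), (1, 4, 4)).transpose(0, 3, 1, 2).astype(np.float32)
        ce = -np.log((p * t).sum(axis=1)).mean()
        assert focal_loss(Tensor(p), t, gamma=0.0, alpha=1.0).item() == pytest.approx(
            ce, rel=1e-4
        )

    def test_dice_perfect_prediction_vanishes(self):
        mask = np.array([[[0, 1], [2, 3]]])
        t = one_hot(mask, 5)
        loss = dice_loss(Tensor(t), t, smooth=1e-9).item()
        # class 4 is absent in both -> its soft dice is smooth/smooth = 1
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_dice_uniform_single_pixel_closed_form(self):
        # uniform 0.2 on a 1-pixel image, one-hot target, smooth -> 0, macro
        # over classes: true class (2*0.2)/(0.2+1) = 1/3, the four absent
        # classes -> 0, so the loss is 1 - (1/3)/5 = 14/15
        t = one_hot(np.array([[[2]]]), 5)
        p = np.full((1, 5, 1, 1), 0.2, np.float32)
        got = dice_loss(Tensor(p), t, smooth=1e-12).item()
        assert got == pytest.approx(1.0 - (1 / 3) / 5, abs=1e-5)

    def test_dice_invariant_to_pixel_permutation(self, rng):
        mask = rng.integers(0, 5, (1, 3, 3))
        t = one_hot(mask, 5)
        p = rng.dirichlet(np.ones(5), (1, 3, 3)).transpose(0, 3, 1, 2).astype(np.float32)
        base = dice_loss(Tensor(p), t).item()
        perm = rng.permutation(9)
        p2 = p.reshape(1, 5, 9)[:, :, perm].reshape(1, 5, 3, 3)
        t2 = t.reshape(1, 5, 9)[:, :, perm].reshape(1, 5, 3, 3)
        assert dice_loss(Tensor(p2), t2).item() == pytest.approx(base, rel=1e-5)

    def test_total_loss_combines_component_oracles(self, rng):
        mask = rng.integers(0, 5, (1, 2, 2))
        dist = rng.random((1, 2, 2)).astype(np.float32)
        p = rng.dirichlet(np.ones(5), (1, 2, 2)).transpose(0, 3, 1, 2).astype(np.float32)
        dpred = rng.random((1, 1, 2, 2)).astype(np.float32)
        cfg = LossConfig()
        t = one_hot(mask, 5)
        expected = (
            mse_loss(Tensor(dpred), dist[:, None]).item()
            + focal_loss(Tensor(p), t, cfg.focal_gamma, cfg.focal_alpha).item()
            + dice_loss(Tensor(p), t, cfg.dice_smooth).item()
        )
        got = total_loss(Tensor(p), Tensor(dpred), mask, dist, cfg).item()
        assert got == pytest.approx(expected, rel=1e-5)

    def test_lambda1_zero_leaves_main_loss_only(self, rng):
        mask = rng.integers(0, 5, (1, 2, 2))
        dist = rng.random((1, 2, 2)).astype(np.float32)
        p = rng.dirichlet(np.ones(5), (1, 2, 2)).transpose(0, 3, 1, 2).astype(np.float32)
        dpred = rng.random((1, 1, 2, 2)).astype(np.float32)
        cfg = LossConfig(lambda1=0.0)
        t = one_hot(mask, 5)
        main = focal_loss(Tensor(p), t).item() + dice_loss(Tensor(p), t, cfg.dice_smooth).item()
        assert total_loss(Tensor(p), Tensor(dpred), mask, dist, cfg).item() == pytest.approx(
            main, rel=1e-5
        )

    def test_shape_mismatch_raises(self, rng):
        p = Tensor(rng.random((1, 5, 4, 4)).astype(np.float32))
        d = Tensor(rng.random((1, 1, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            total_loss(p, d, np.zeros((1, 8, 8), np.int64), np.zeros((1, 4, 4), np.float32))


class TestTraining:
    def test_auxiliary_gradients_reach_encoder(self, untrained_seg_model, rng):
        """The distance head shares the trunk: its loss moves encoder weights."""
        model = untrained_seg_model
        model.zero_grad()
        x = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
        _, dist = model(x)
        target = rng.random((2, 1, 64, 64)).astype(np.float32)
        ((dist - Tensor(target)) ** 2).mean().backward()
        enc_norm = sum(
            float(np.abs(p.grad).sum())
            for p in model.encoder.parameters()
            if p.grad is not None
        )
        assert enc_norm > 0
        model.zero_grad()

    def test_seeded_training_is_reproducible(self, seg_tiles):
        def run():
            m = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"), seed=3)
            cfg = SegTrainConfig(epochs=3, batch_size=8, seed=3, max_steps=3)
            _, h = train_segmentation(m, seg_tiles, cfg)
            return h["train_loss"]

        assert run() == run()

    def test_loss_history_finite(self, seg_tiles):
        m = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"), seed=4)
        cfg = SegTrainConfig(epochs=3, batch_size=8, seed=4, max_steps=3)
        _, h = train_segmentation(m, seg_tiles, cfg)
        assert np.isfinite(h["train_loss"]).all()

    def test_empty_dataset_raises(self):
        m = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"))
        with pytest.raises(ValueError, match="empty"):
            train_segmentation(m, [], SegTrainConfig(epochs=1))

    def test_predict_tile_output_contract(self, trained_seg_model, seg_tiles):
        out = predict_tile(trained_seg_model, seg_tiles[0].image)
        assert out.class_probs.shape == (64, 64, 5)
        assert out.distance_pred.shape == (64, 64)
        assert out.mask.dtype == np.uint8
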