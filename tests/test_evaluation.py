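"""Overlap metrics, SSIM, confusion tables and entropy-TOPSIS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oraltils.evaluation import (
    SSIMParams,
    confusion_matrix,
    dice,
    dominant_cell_label,
    entropy_weights,
    iou,
    load_reference_matrix,
    per_class_metrics,
    rank_models,
    ssim,
    topsis_rank,
)


class TestOverlap:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 5, (16, 16)).astype(np.uint8)
        for c in range(5):
            if (m == c).any():
                assert iou(m, m, c) == 1.0
                assert dice(m, m, c) == 1.0

    def test_disjoint_sets_zero(self):
        a = np.array([[1, 1, 0, 0]])
        b = np.array([[0, 0, 1, 1]])
        assert iou(a, b, 1) == 0.0
        assert dice(a, b, 1) == 0.0

    def test_half_vs_three_quarters(self):
        pred = np.array([[1, 1, 0, 0]])
        gt = np.array([[1, 1, 1, 0]])
        assert iou(pred, gt, 1) == pytest.approx(2 / 3)
        assert dice(pred, gt, 1) == pytest.approx(0.8)

    def test_empty_class_defined_as_one(self):
        z = np.zeros((4, 4), np.uint8)
        assert iou(z, z, 3) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dice_iou_identity(self, seed):
        r = np.random.default_rng(seed)
        a = (r.random((8, 8)) < 0.5).astype(np.uint8)
        b = (r.random((8, 8)) < 0.5).astype(np.uint8)
        i, d = iou(a, b, 1), dice(a, b, 1)
        assert d == pytest.approx(2 * i / (1 + i))
        assert d >= i


class TestDominantLabel:
    def test_majority_wins(self):
        m = np.array([3] * 6 + [1] * 3 + [2] * 1).reshape(2, 5)
        assert dominant_cell_label(m) == "stroma"

    def test_single_pixel(self):
        m = np.zeros((4, 4), np.uint8)
        m[0, 0] = 1
        assert dominant_cell_label(m) == "tumour"

    def test_tie_breaks_in_class_order(self):
        m = np.array([[1, 2], [0, 0]], np.uint8)
        assert dominant_cell_label(m) == "tumour"

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no cellular content"):
            dominant_cell_label(np.zeros((4, 4), np.uint8))

    def test_generator_round_trip(self, small_synth_config):
        """Tiles generated TIL-dominant are labelled tils, for many seeds."""
        from dataclasses import replace

        from oraltils.synthetic import generate_cell_tile

        cfg = replace(
            small_synth_config,
            per_class_target_fraction={1: 0.04, 2: 0.20, 3: 0.04, 4: 0.0},
        )
        for seed in range(30):
            tile = generate_cell_tile(cfg, seed)
            assert dominant_cell_label(tile.mask) == "tils"


class TestPerClassMetrics:
    def test_identity_matrix_all_100(self):
        t = per_class_metrics(np.diag([5, 7, 9]))
        assert (t[["accuracy", "precision", "recall", "f1"]].to_numpy() == 100.0).all()

    def test_printed_counts_reproduce_reported_recalls(self):
        # 503 of 520 and 444 of 454 retrieved -> 96.73% and 97.80%
        assert 100 * 503 / 520 == pytest.approx(96.73, abs=0.005)
        cm = np.array([[503, 12, 5], [20, 488, 8], [5, 5, 444]])
        t = per_class_metrics(cm)
        assert t.loc["class_0", "accuracy"] == pytest.approx(96.73, abs=0.005)
        assert t.loc["class_2", "accuracy"] == pytest.approx(97.80, abs=0.005)

    def test_hand_computed_toy_matrix(self):
        cm = np.array([[2, 1, 0], [0, 3, 1], [1, 0, 2]])
        t = per_class_metrics(cm, percent=False)
        assert t.loc["class_0", "recall"] == pytest.approx(2 / 3)
        assert t.loc["class_0", "precision"] == pytest.approx(2 / 3)
        assert t.loc["class_1", "precision"] == pytest.approx(3 / 4)
        assert t.loc["overall", "accuracy"] == pytest.approx(7 / 10)
        # accuracy column equals recall per class
        assert (t["accuracy"].iloc[:3] == t["recall"].iloc[:3]).all()

    def test_empty_column_warns_and_zeroes(self):
        cm = np.array([[3, 0], [2, 0]])
        with pytest.warns(UserWarning):
            t = per_class_metrics(cm, percent=False)
        assert t.loc["class_1", "precision"] == 0.0


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        assert ssim(x, x) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        a, b = 100.0, 50.0
        p = SSIMParams()
        x = np.full((8, 8), a)
        y = np.full((8, 8), b)
        lum = (2 * a * b + p.c1) / (a**2 + b**2 + p.c1)
        assert ssim(x, y, p) == pytest.approx(lum)

    def test_matches_scalar_formula_oracle(self, rng):
        x = rng.integers(0, 255, (8, 8)).astype(np.float64)
        y = rng.integers(0, 255, (8, 8)).astype(np.float64)
        p = SSIMParams()
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        expected = ((2 * mx * my + p.c1) * (2 * cov + p.c2)) / (
            (mx**2 + my**2 + p.c1) * (vx + vy + p.c2)
        )
        assert ssim(x, y, p) == pytest.approx(expected, rel=1e-12)


class TestEntropyWeights:
    def test_constant_criterion_gets_zero_weight(self):
        m = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        w = entropy_weights(m)
        assert w["a"] == pytest.approx(0.0, abs=1e-12)
        assert w["b"] == pytest.approx(1.0)

    def test_hand_computed_3x2(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]})
        p = np.array([1, 2, 3]) / 6
        e_a = -(p * np.log(p)).sum() / np.log(3)
        w = entropy_weights(m)
        assert w["a"] == pytest.approx((1 - e_a) / (1 - e_a))  # only divergent column
        assert w.sum() == pytest.approx(1.0)

    def test_all_constant_raises(self):
        m = pd.DataFrame({"a": [2.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            entropy_weights(m)

    def test_nonnegative_and_normalized(self, rng):
        m = pd.DataFrame(rng.uniform(1, 100, (6, 4)))
        w = entropy_weights(m)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0)


class TestTopsis:
    def test_dominant_alternative_scores_one(self):
        m = pd.DataFrame(
            {"a": [9.0, 5.0, 1.0], "b": [8.0, 4.0, 2.0]}, index=["best", "mid", "worst"]
        )
        r = topsis_rank(m, entropy_weights(m))
        assert r.loc["best", "closeness"] == pytest.approx(1.0)
        assert r.loc["best", "rank"] == 1
        assert r.loc["worst", "closeness"] == pytest.approx(0.0)

    def test_scale_invariance_of_closeness(self, rng):
        m = pd.DataFrame(rng.uniform(1, 10, (5, 3)))
        w = pd.Series([0.5, 0.3, 0.2])
        base = topsis_rank(m, w)["closeness"]
        m2 = m.copy()
        m2[0] *= 37.5  # vector normalization cancels positive column scaling
        np.testing.assert_allclose(base, topsis_rank(m2, w)["closeness"], atol=1e-12)

    def test_single_alternative_raises(self):
        with pytest.raises(ValueError):
            topsis_rank(pd.DataFrame({"a": [1.0]}), np.array([1.0]))

    def test_weights_must_sum_to_one(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="sum to 1"):
            topsis_rank(m, np.array([0.9, 0.5]))


class TestReferenceMatrices:
    def test_blocks_load_with_12_alternatives_4_criteria(self):
        for block in ("none_to_very_less", "slight", "moderate_to_marked", "overall"):
            m = load_reference_matrix(block)
            assert m.shape == (12, 4)
            assert (m.to_numpy() > 0).all()

    def test_overall_block_has_a_dominant_alternative(self):
        m = load_reference_matrix("overall")
        best = m.loc["fused (lr=0.001, adam)"]
        assert (best == m.max()).all()
        r = rank_models(m)
        assert r.index[0] == "fused (lr=0.001, adam)"
        assert r["closeness"].iloc[0] == pytest.approx(1.0)


def test_confusion_matrix_counts():
    y = np.array([0, 0, 1, 2, 2, 2])
    p = np.array([0, 1, 1, 2, 0, 2])
    cm = confusion_matrix(y, p, 3)
    np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 1, 0], [1, 0, 2]])
    assert (cm.sum(axis=1) == np.bincount(y, minlength=3)).all()


class TestSelfConsistency:
    """Prediction agreement between original and perturbed tiles."""

    @staticmethod
    def _threshold_segmenter(img):
        """Per-pixel colour thresholder: exactly flip-equivariant."""
        dark = img.astype(np.float32).mean(axis=-1)
        out = np.zeros(img.shape[:2], np.uint8)
        out[dark < 100] = 2
        out[(dark >= 100) & (dark < 170)] = 1
        return out

    @staticmethod
    def _tiles(n=4, seed=0):
        from oraltils.synthetic import SynthConfig, generate_cell_tile

        cfg = SynthConfig(tile_size=64, cell_radius_range=(3, 6))
        return [generate_cell_tile(cfg, seed + i).image for i in range(n)]

    def test_equivariant_model_perfect_under_flip(self):
        from oraltils.evaluation import self_consistency

        table = self_consistency(self._threshold_segmenter, self._tiles(),
                                 transform="horizontal_flip")
        assert (table["iou"] == 1.0).all()
        assert np.allclose(table["ssim"], 1.0)

    def test_zero_amplitude_noise_is_identity(self):
        from oraltils.evaluation import self_consistency

        table = self_consistency(self._threshold_segmenter, self._tiles(),
                                 transform="gaussian_noise", noise_sigma=0.0, seed=3)
        assert (table["iou"] == 1.0).all()
        assert np.allclose(table["ssim"], 1.0)

    def test_agreement_degrades_with_noise_amplitude(self):
        from oraltils.evaluation import self_consistency

        tiles = self._tiles(6)
        means = [
            self_consistency(self._threshold_segmenter, tiles,
                             transform="gaussian_noise", noise_sigma=s, seed=5)["iou"].mean()
            for s in (0.0, 12.0, 40.0)
        ]
        assert means[0] >= means[1] - 1e-9
        assert means[1] >= means[2] - 1e-9

    def test_trained_model_consistency_in_range(self, trained_seg_model):
        from oraltils.evaluation import self_consistency
        from oraltils.segmentation import predict_tile

        table = self_consistency(
            lambda img: predict_tile(trained_seg_model, img).mask,
            self._tiles(3), transform="horizontal_flip",
        )
        assert ((table["iou"] >= 0) & (table["iou"] <= 1)).all()
        assert ((table["ssim"] >= -1) & (table["ssim"] <= 1)).all()

    def test_unknown_transform_rejected(self):
        from oraltils.evaluation import self_consistency

        with pytest.raises(ValueError, match="transform"):
            self_consistency(self._threshold_segmenter, [], transform="rotate")
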