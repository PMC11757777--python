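"""End-to-end two-stage pipeline runner.

Mirrors the full workflow on synthetic data: generate a source domain with
masks, pretrain the dual-head segmenter, pseudo-label a colour-shifted
target domain at high confidence, fine-tune the last layers, densify
labelled fields of view into cellular density maps, pretrain the two
modality classifiers, train the fusion classifier, and evaluate all three
with confusion matrices, per-class metrics and an entropy-weighted TOPSIS
ranking.  Every stage draws its randomness from a per-stage child of the
single run seed, and the artifact directory records the exact config, so
reruns reproduce the metrics report bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .classifier import (
    ClassifierConfig,
    ClsTrainConfig,
    evaluate_accuracy,
    predict_proba,
    pretrain_encoder,
    train_fusion,
)
from .config import RunConfig, dump_config
from .evaluation import confusion_matrix, per_class_metrics, rank_models
from .segmentation import LossConfig, SegModelConfig, SegTrainConfig, build_tilseg, train_segmentation
from .synthetic import SynthConfig, generate_cell_tile, generate_fov_sample
from .weak_supervision import PseudoMaskConfig, densify_fov, fine_tune, generate_pseudo_masks

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("oraltils")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan the run seed out to independent per-stage seeds."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _resize_uint8(img: np.ndarray, size: int, nearest: bool) -> np.ndarray:
    out = resize(img, (size, size), order=0 if nearest else 1,
                 preserve_range=True, anti_aliasing=not nearest)
    return np.clip(out, 0, 255).astype(np.uint8)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full two-stage workflow; returns the artifact directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config.yaml")
    seeds = _stage_seeds(config.seed)
    log.info("run seed %d -> stage seeds %s", config.seed, seeds)
    metrics: dict = {"seed": config.seed}

    s1 = config.stage1
    synth_cfg = SynthConfig(
        tile_size=s1.tile_size,
        cell_radius_range=(max(2, s1.tile_size // 24), max(4, s1.tile_size // 10)),
    )
    # a colour-shifted target domain: same structure, different stain balance
    target_cfg = replace(
        synth_cfg,
        background_color=(226, 214, 232),
        class_colors={1: (120, 50, 140), 2: (45, 40, 115), 3: (190, 115, 160), 4: (110, 110, 110)},
    )

    stage = "synth"
    try:
        rng = np.random.default_rng(seeds[0])
        tile_seeds = rng.integers(0, 2**31 - 1, size=s1.n_train + s1.n_val)
        tiles = [generate_cell_tile(synth_cfg, int(s)) for s in tile_seeds]
        train_tiles, val_tiles = tiles[: s1.n_train], tiles[s1.n_train :]

        stage = "seg-pretrain"
        model = build_tilseg(
            SegModelConfig(input_size=s1.input_size, encoder_variant=s1.encoder_variant),
            seed=seeds[1],
        )
        seg_cfg = SegTrainConfig(
            epochs=s1.epochs, batch_size=s1.batch_size, optimizer=s1.optimizer,
            learning_rate=s1.learning_rate, patience=s1.patience, seed=seeds[1],
            loss=LossConfig(**s1.loss.model_dump()),
        )
        model, hist = train_segmentation(model, train_tiles, seg_cfg, val_tiles or None)
        metrics["seg_pretrain_final_loss"] = hist["train_loss"][-1]

        stage = "pseudo"
        pseudo_rng = np.random.default_rng(seeds[2])
        pseudo_tiles = [
            generate_cell_tile(target_cfg, int(s))
            for s in pseudo_rng.integers(0, 2**31 - 1, size=max(s1.n_train // 2, 8))
        ]
        pseudo = generate_pseudo_masks(
            model,
            [t.image for t in pseudo_tiles],
            PseudoMaskConfig(s1.confidence_tau, s1.min_cellular_fraction),
        )
        metrics["pseudo_patches_kept"] = len(pseudo)

        stage = "finetune"
        if pseudo and s1.finetune_epochs > 0:
            ft_cfg = SegTrainConfig(
                epochs=s1.finetune_epochs, batch_size=s1.finetune_batch_size,
                optimizer=s1.optimizer, learning_rate=s1.learning_rate,
                patience=s1.patience, seed=seeds[3],
                loss=LossConfig(**s1.loss.model_dump()),
            )
            model, _ = fine_tune(model, pseudo, s1.unfreeze_last_n, ft_cfg)
        model.unfreeze()

        stage = "densify"
        s2 = config.stage2
        fov_cfg = replace(target_cfg, fov_size=s2.fov_size)
        fov_rng = np.random.default_rng(seeds[4])
        fov_seeds = fov_rng.integers(0, 2**31 - 1, size=3 * s2.n_per_class)
        fovs = [
            generate_fov_sample(fov_cfg, cls, int(fov_seeds[cls * s2.n_per_class + i]))
            for cls in range(3)
            for i in range(s2.n_per_class)
        ]
        samples = []
        for fov in fovs:
            density = densify_fov(
                model, fov.image, tile=s1.tile_size, seg_size=s1.input_size
            )
            samples.append(
                (
                    _resize_uint8(fov.image, s2.input_size, nearest=False),
                    _resize_uint8(density, s2.input_size, nearest=True),
                    fov.label,
                )
            )

        stage = "stage2-split"
        split_rng = np.random.default_rng(seeds[5])
        order = split_rng.permutation(len(samples))
        n_test = max(3, int(round(s2.test_fraction * len(samples))))
        test_idx, train_idx = order[:n_test], order[n_test:]
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in test_idx]
        if not train or not test:
            raise ValueError("stage-2 dataset too small to split")

        stage = "cls-pretrain"
        cls_cfg = ClassifierConfig(
            input_size=s2.input_size, encoder_variant=s2.encoder_variant,
            dropout_rate=s2.dropout_rate,
        )
        tr_cfg = ClsTrainConfig(
            epochs=s2.epochs, batch_size=s2.batch_size, optimizer=s2.optimizer,
            learning_rate=s2.learning_rate, seed=seeds[6], augment=s2.augment,
        )
        img_model, _ = pretrain_encoder(
            "image", [(a, y) for a, _, y in train], cls_cfg, tr_cfg, seed=seeds[6]
        )
        cell_model, _ = pretrain_encoder(
            "cell", [(b, y) for _, b, y in train], cls_cfg, tr_cfg, seed=seeds[6] + 1
        )

        stage = "fuse-train"
        fused, _ = train_fusion(img_model, cell_model, train, cls_cfg, tr_cfg, seed=seeds[7])

        stage = "evaluate"
        y = np.array([t[2] for t in test])
        imgs = np.stack([t[0] for t in test])
        cells = np.stack([t[1] for t in test])
        acc = {
            "image_only": evaluate_accuracy(img_model, y, imgs),
            "cell_density_only": evaluate_accuracy(cell_model, y, cells),
            "fused": evaluate_accuracy(fused, y, imgs, cells),
        }
        metrics["test_accuracy"] = acc
        pred = predict_proba(fused, imgs, cells).argmax(axis=1)
        cm = confusion_matrix(y, pred, 3)
        table = per_class_metrics(cm, list(cls_cfg.label_order))
        metrics["fused_confusion_matrix"] = cm.tolist()
        table.to_csv(out / "fused_per_class_metrics.csv")

        stage = "mcda"
        rows = {}
        for name, mdl, args in [
            ("image_only", img_model, (imgs,)),
            ("cell_density_only", cell_model, (cells,)),
            ("fused", fused, (imgs, cells)),
        ]:
            p = predict_proba(mdl, *args).argmax(axis=1)
            t = per_class_metrics(confusion_matrix(y, p, 3), list(cls_cfg.label_order))
            rows[name] = t.loc["overall", ["accuracy", "precision", "recall", "f1"]]
        import pandas as pd

        dm = pd.DataFrame(rows).T.clip(lower=0.01)  # strictly positive for entropy weights
        try:
            ranking = rank_models(dm)
            ranking.to_csv(out / "mcda_ranking.csv")
            metrics["mcda_closeness"] = ranking["closeness"].round(6).to_dict()
        except ValueError as e:  # all criteria constant at tiny scale
            metrics["mcda_closeness"] = f"undefined: {e}"
    except Exception as e:  # noqa: BLE001 - reported with the failing stage
        raise PipelineError(stage, e) from e

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
    manifest = [str(p.relative_to(out)) for p in sorted(out.rglob("*")) if p.is_file()]
    (out / "artifact_manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return out
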