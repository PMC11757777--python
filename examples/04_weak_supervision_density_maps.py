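"""Weak supervision: pseudo-masks, tail fine-tuning, FOV densification.

Pretrains on one stain domain, pseudo-labels a colour-shifted domain at
confidence > 0.95, fine-tunes the last 20 layers, and renders a large-FOV
cellular density map whose green (TIL) pixel fraction is compared with the
ground truth.  Runtime: a couple of minutes.
"""

from dataclasses import replace

import numpy as np

from oraltils.evaluation import iou
from oraltils.segmentation import (
    SegModelConfig, SegTrainConfig, build_tilseg, predict_tile, train_segmentation,
)
from oraltils.synthetic import SynthConfig, generate_cell_tile, generate_fov_sample
from oraltils.weak_supervision import (
    PseudoMaskConfig, densify_fov, fine_tune, generate_pseudo_masks,
)

source = SynthConfig(tile_size=64, cell_radius_range=(3, 6))
shifted = replace(
    source,
    background_color=(216, 186, 214),
    class_colors={1: (100, 40, 120), 2: (35, 30, 100), 3: (170, 100, 150), 4: (100, 100, 100)},
)

model = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"), seed=0)
model, _ = train_segmentation(
    model,
    [generate_cell_tile(source, s) for s in range(200)],
    SegTrainConfig(epochs=8, batch_size=8, learning_rate=0.005, seed=0),
)

target_tiles = [generate_cell_tile(shifted, 50_000 + s) for s in range(200)]
held_out = [generate_cell_tile(shifted, 90_000 + s) for s in range(20)]


def foreground_iou(m):
    vals = []
    for s in held_out:
        pred = predict_tile(m, s.image).mask
        vals.append(np.mean([iou(pred, s.mask, c) for c in (1, 2, 3) if (s.mask == c).any()]))
    return float(np.mean(vals))


before = foreground_iou(model)
pseudo = generate_pseudo_masks(
    model, [t.image for t in target_tiles], PseudoMaskConfig(0.95, 0.01)
)
print(f"pseudo-labelled patches kept: {len(pseudo)}/200 (confidence > 0.95)")
model, _ = fine_tune(
    model, pseudo, unfreeze_last_n=20,
    train_cfg=SegTrainConfig(epochs=3, batch_size=16, learning_rate=0.001, seed=1),
)
model.unfreeze()
print(f"shifted-domain foreground IoU: {before:.3f} before -> {foreground_iou(model):.3f} "
      "after fine-tuning (higher = better adaptation)")

fov = generate_fov_sample(replace(shifted, fov_size=128), 2, seed=11)
density = densify_fov(model, fov.image, tile=64, seg_size=64)
green = (density == np.array([0, 255, 0], np.uint8)).all(axis=-1).mean()
print(f"densified FOV: green (TIL) fraction {green:.3f} vs ground truth "
      f"{(fov.mask == 2).mean():.3f}")
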