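"""Dual-encoder fusion versus single-modality TIL grading (a few minutes).

Builds the complementarity benchmark — the density map separates grade 0
from {1,2}, an image-only texture cue separates grade 2 — trains the two
single-modality classifiers and the fused model, and prints their held-out
accuracies.  The fused accuracy exceeding both singles is the point: each
modality alone is insufficient by construction.
"""

import numpy as np

from oraltils.classifier import (
    ClassifierConfig, ClsTrainConfig, evaluate_accuracy, pretrain_encoder, train_fusion,
)
from oraltils.pipeline import _resize_uint8
from oraltils.synthetic import SynthConfig, generate_benchmark_samples
from oraltils.weak_supervision import render_density_map

cfg = SynthConfig(tile_size=64, cell_radius_range=(3, 6), fov_size=128)


def prep(samples, size=32):
    return [
        (
            _resize_uint8(s.image, size, nearest=False),
            _resize_uint8(render_density_map(s.mask), size, nearest=True),
            s.label,
        )
        for s in samples
    ]


train = prep(generate_benchmark_samples(40, cfg, seed=11))
test = prep(generate_benchmark_samples(15, cfg, seed=99))

ccfg = ClassifierConfig(input_size=32, encoder_variant="micro")
pcfg = ClsTrainConfig(epochs=40, batch_size=16, learning_rate=0.003, seed=0,
                      augment=True, stain_sigma=0.0)
image_model, _ = pretrain_encoder("image", [(a, y) for a, _, y in train], ccfg, pcfg, seed=1)
cell_model, _ = pretrain_encoder("cell", [(b, y) for _, b, y in train], ccfg, pcfg, seed=2)
fcfg = ClsTrainConfig(epochs=80, batch_size=16, learning_rate=0.005, seed=0,
                      augment=True, stain_sigma=0.0)
fused, _ = train_fusion(image_model, cell_model, train, ccfg, fcfg, seed=3)

y = np.array([t[2] for t in test])
imgs = np.stack([t[0] for t in test])
cells = np.stack([t[1] for t in test])
print(f"image-only accuracy : {evaluate_accuracy(image_model, y, imgs):.3f}")
print(f"cell-map-only       : {evaluate_accuracy(cell_model, y, cells):.3f}")
print(f"fused               : {evaluate_accuracy(fused, y, imgs, cells):.3f}")
print("(each single modality is capped near 2/3 by construction; "
      "fusion can resolve all three grades)")
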