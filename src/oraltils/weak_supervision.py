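"""Weak-supervision loop and cellular-density-map rendering.

The segmentation model is first trained on a source domain with real
masks; it then labels the unannotated target domain itself: per pixel the
argmax class is kept only when its probability clears a high confidence
threshold (default 0.95), everything else falls back to background, and
patches with almost no confident cellular content are dropped.  The model
is fine-tuned on these pseudo-masks with only its last few layers
unfrozen, which adapts colour statistics without forgetting shape priors.

Density maps render a label mask under a fixed palette (tumour red, TILs
green, stroma dark pink, background and "others" black); large fields of
view are densified tile-by-tile and stitched back together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .patches import Tile, compute_distance_map, extract_tiles, stitch_tiles
from .segmentation import (
    SegTrainConfig,
    TILSegMobileViT,
    train_segmentation,
)
from .nn.tensor import Tensor

__all__ = [
    "PseudoMaskConfig",
    "Palette",
    "DEFAULT_PALETTE",
    "generate_pseudo_masks",
    "fine_tune",
    "render_density_map",
    "invert_density_map",
    "densify_fov",
    "PseudoSample",
]


@dataclass(frozen=True)
class PseudoMaskConfig:
    confidence_tau: float = 0.95
    min_cellular_fraction: float = 0.01

    def validate(self) -> None:
        if not (0.0 < self.confidence_tau < 1.0):
            raise ValueError("confidence_tau must lie in (0,1)")
        if not (0.0 <= self.min_cellular_fraction <= 1.0):
            raise ValueError("min_cellular_fraction must lie in [0,1]")


@dataclass(frozen=True)
class Palette:
    """Class -> RGB colour map for density-map rendering."""

    colors: tuple[tuple[int, int, int], ...] = (
        (0, 0, 0),  # background: black
        (255, 0, 0),  # tumour: red
        (0, 255, 0),  # TILs: green
        (255, 20, 147),  # stroma: dark pink
        (0, 0, 0),  # others: black (not a scored cell type)
    )

    def validate(self) -> None:
        fg = self.colors[1:4]
        if len(set(fg)) != 3:
            raise ValueError("palette colours for classes 1-3 must be pairwise distinct")

    def as_array(self) -> np.ndarray:
        return np.array(self.colors, np.uint8)


DEFAULT_PALETTE = Palette()


@dataclass
class PseudoSample:
    image: np.ndarray
    mask: np.ndarray
    distance: np.ndarray

    @property
    def seed(self) -> int:  # allows reuse of the segmentation training loop
        return -1


def _predict_batch(model: TILSegMobileViT, images: np.ndarray) -> np.ndarray:
    """images (N, H, W, 3) uint8 -> class probabilities (N, H, W, C)."""
    x = np.moveaxis(images.astype(np.float32) / 255.0, -1, 1)
    model.eval()
    probs, _ = model(Tensor(x))
    return np.moveaxis(probs.data, 1, -1)


def generate_pseudo_masks(
    model: TILSegMobileViT,
    tiles,
    cfg: PseudoMaskConfig | None = None,
    batch_size: int = 8,
) -> list[PseudoSample]:
    """Self-label tiles with high-confidence predictions.

    A pixel receives the argmax class only when that class's probability
    exceeds ``confidence_tau``; sub-threshold pixels become background.
    The distance target is recomputed from the pseudo-mask itself so both
    heads see a consistent supervision signal.  Patches whose confident
    cellular fraction is below ``min_cellular_fraction`` are dropped.
    """
    cfg = cfg or PseudoMaskConfig()
    cfg.validate()
    images = [t.pixels if isinstance(t, Tile) else np.asarray(t) for t in tiles]
    out: list[PseudoSample] = []
    for i in range(0, len(images), batch_size):
        chunk = np.stack(images[i : i + batch_size])
        probs = _predict_batch(model, chunk)
        conf = probs.max(axis=-1)
        labels = probs.argmax(axis=-1).astype(np.uint8)
        labels[conf <= cfg.confidence_tau] = 0
        for img, mask in zip(chunk, labels):
            if (mask > 0).mean() < cfg.min_cellular_fraction:
                continue
            out.append(PseudoSample(img, mask, compute_distance_map(mask)))
    return out


def fine_tune(
    model: TILSegMobileViT,
    pseudo_dataset,
    unfreeze_last_n: int | None = None,
    train_cfg: SegTrainConfig | None = None,
    val_dataset=None,
) -> tuple[TILSegMobileViT, dict]:
    """Adapt a pretrained model on pseudo-labels, updating only the tail.

    All layers are frozen except the last ``unfreeze_last_n`` entries of
    the flattened parameter-carrying layer list (output side backwards).
    ``unfreeze_last_n = 0`` freezes everything (a no-op training run).
    """
    n = model.config.unfreeze_last_n if unfreeze_last_n is None else unfreeze_last_n
    layers = model.leaf_layers()
    if n > len(layers):
        raise ValueError(f"unfreeze_last_n={n} exceeds the {len(layers)}-layer model")
    model.freeze()
    for layer in layers[len(layers) - n :]:
        for p in layer._params.values():
            p.trainable = True
    cfg = train_cfg or SegTrainConfig(epochs=20, batch_size=16)
    return train_segmentation(model, pseudo_dataset, cfg, val_dataset)


def render_density_map(mask: np.ndarray, palette: Palette = DEFAULT_PALETTE) -> np.ndarray:
    """Colour a label mask: per-pixel palette lookup, bijective on classes 1-3."""
    palette.validate()
    return palette.as_array()[mask]


def invert_density_map(density: np.ndarray, palette: Palette = DEFAULT_PALETTE) -> np.ndarray:
    """Recover labels 1-3 from a rendered map (background/others both -> 0)."""
    out = np.zeros(density.shape[:2], np.uint8)
    for cls in (1, 2, 3):
        out[(density == np.array(palette.colors[cls], np.uint8)).all(axis=-1)] = cls
    return out


def densify_fov(
    model: TILSegMobileViT,
    fov_image: np.ndarray,
    tile: int = 256,
    seg_size: int = 128,
    palette: Palette = DEFAULT_PALETTE,
    batch_size: int = 8,
) -> np.ndarray:
    """Tile a large FOV, segment each tile, render, and stitch the map.

    Tiles of side ``tile`` are bilinearly resized to the network input
    ``seg_size``, predicted, rendered under the palette, resized back with
    nearest-neighbour interpolation (labels are categorical — no invented
    colours), and stitched at their origins; any right/bottom margin the
    tile grid does not cover stays black.
    """
    h, w = fov_image.shape[:2]
    if h < tile or w < tile:
        raise ValueError("field of view is smaller than one tile")
    tiles = extract_tiles(fov_image, tile, tile)
    rendered: list[Tile] = []
    for i in range(0, len(tiles), batch_size):
        chunk = tiles[i : i + batch_size]
        small = np.stack(
            [
                resize(t.pixels, (seg_size, seg_size), order=1, preserve_range=True,
                       anti_aliasing=True).astype(np.float32)
                for t in chunk
            ]
        )
        probs = _predict_batch(model, small.astype(np.uint8))
        masks = probs.argmax(axis=-1).astype(np.uint8)
        for t, m in zip(chunk, masks):
            if seg_size != tile:
                m = resize(m, (tile, tile), order=0, preserve_range=True,
                           anti_aliasing=False).astype(np.uint8)
            rendered.append(Tile(render_density_map(m, palette), t.origin, t.parent_size))
    return stitch_tiles(rendered)
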