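"""Tile extraction/stitching, mask relabeling, distance maps and splits.

This module holds the data-preparation steps shared by both stages of the
TIL-scoring pipeline: carving large fields of view (FOVs) into fixed-size
tiles and reassembling them, collapsing fine-grained nucleus categories
into the five working labels, deriving the normalized Euclidean distance
map used as the auxiliary regression target, filtering tiles by tissue
coverage, and seeded train/validation/test splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Tile",
    "SplitSpec",
    "STAGE1_SPLIT",
    "STAGE2_SPLIT",
    "CATEGORY_TO_LABEL",
    "extract_tiles",
    "tile_grid_count",
    "stitch_tiles",
    "relabel_mask",
    "compute_distance_map",
    "tissue_coverage",
    "passes_tissue_filter",
    "split_dataset",
    "rank_by_stain_variance",
]

#: working label alphabet: 0 background, 1 tumour, 2 TILs, 3 stroma, 4 others
N_CLASSES = 5

#: grouping of named nucleus categories into the working labels
CATEGORY_TO_LABEL: dict[str, int] = {
    "background": 0,
    "cancer_nucleus": 1,
    "lymphocyte_nucleus": 2,
    "plasma_large_til_nucleus": 2,
    "stromal_nucleus": 3,
    "large_stromal_nucleus": 3,
    "other_nucleus": 4,
    "unknown_ambiguous_nucleus": 4,
}


@dataclass
class Tile:
    """A window cut from a parent raster, carrying its provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8 or (H, W) for masks
    origin: tuple[int, int]  # (row, col) in the parent image, 0-based
    parent_size: tuple[int, int]

    def __post_init__(self):
        r, c = self.origin
        h, w = self.pixels.shape[:2]
        if r < 0 or c < 0 or r + h > self.parent_size[0] or c + w > self.parent_size[1]:
            raise ValueError("tile window falls outside its parent image")


@dataclass(frozen=True)
class SplitSpec:
    """Fractions for a seeded shuffle split; remainder rounding goes to train."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        f = self.fractions
        if any(x < 0 or x > 1 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split fractions must lie in [0,1] and sum to 1")


STAGE1_SPLIT = SplitSpec((0.8, 0.1, 0.1))
STAGE2_SPLIT = SplitSpec((0.9, 0.1, 0.0))


def tile_grid_count(height: int, width: int, tile: int, stride: int) -> int:
    """Number of full tile windows in an image (partial windows discarded)."""
    if tile > height or tile > width:
        return 0
    return ((height - tile) // stride + 1) * ((width - tile) // stride + 1)


def extract_tiles(image: np.ndarray, tile: int, stride: int | None = None) -> list[Tile]:
    """Enumerate full tile windows row-major; ``stride == tile`` means
    non-overlapping. Windows that would cross the image border are dropped.
    """
    if tile < 1:
        raise ValueError("tile size must be >= 1")
    stride = tile if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    out: list[Tile] = []
    for r in range(0, h - tile + 1, stride):
        for c in range(0, w - tile + 1, stride):
            out.append(Tile(image[r : r + tile, c : c + tile].copy(), (r, c), (h, w)))
    return out


def stitch_tiles(tiles: Sequence[Tile]) -> np.ndarray:
    """Place tiles back at their origins; uncovered pixels stay zero.

    Raises on overlapping tiles or inconsistent parent sizes.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    parent = tiles[0].parent_size
    if any(t.parent_size != parent for t in tiles):
        raise ValueError("tiles disagree on parent size")
    shape = parent + tiles[0].pixels.shape[2:]
    out = np.zeros(shape, dtype=tiles[0].pixels.dtype)
    covered = np.zeros(parent, dtype=bool)
    for t in tiles:
        r, c = t.origin
        h, w = t.pixels.shape[:2]
        if covered[r : r + h, c : c + w].any():
            raise ValueError(f"tile at {t.origin} overlaps a previously placed tile")
        covered[r : r + h, c : c + w] = True
        out[r : r + h, c : c + w] = t.pixels
    return out


def relabel_mask(
    source_mask: np.ndarray,
    code_to_category: Mapping[int, str],
    category_map: Mapping[str, int] = CATEGORY_TO_LABEL,
) -> np.ndarray:
    """Map dataset-specific nucleus codes to the 5-label working alphabet.

    ``code_to_category`` names each raw integer code; ``category_map`` then
    groups the names (lymphocyte and plasma/large-TIL nuclei both become
    TILs, the two stromal categories become stroma, anything unknown or
    ambiguous becomes "others").  Unmapped codes raise, listing the code.
    """
    present = np.unique(source_mask)
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=np.uint8)
    for code in present:
        code = int(code)
        if code not in code_to_category:
            raise KeyError(f"source mask contains unmapped code {code}")
        name = code_to_category[code]
        if name not in category_map:
            raise KeyError(f"category {name!r} missing from category map")
        lut[code] = category_map[name]
    return lut[source_mask]


def compute_distance_map(mask: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Normalized Euclidean distance transform of the cellular foreground.

    The mask is binarized (any nucleus class -> 1), each foreground pixel
    gets its Euclidean distance to the nearest background pixel, and the
    result is scaled by the per-patch maximum so nucleus centres approach 1
    while boundary-adjacent pixels stay low.  An all-background mask yields
    an all-zero map.
    """
    fg = mask > 0
    dist = ndimage.distance_transform_edt(fg).astype(np.float32)
    if normalize:
        m = dist.max()
        if m > 0:
            dist /= m
    return dist


def tissue_coverage(
    tile: np.ndarray, luminance_max: float = 220.0, saturation_min: float = 0.05
) -> float:
    """Fraction of pixels that look like tissue rather than glass/background.

    A pixel counts as tissue when its luminance is below ``luminance_max``
    (out of 255) or its RGB saturation exceeds ``saturation_min`` — white
    or near-white glass fails both.
    """
    rgb = tile.astype(np.float32)
    lum = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-6), 0.0)
    tissue = (lum < luminance_max) | (sat > saturation_min)
    return float(tissue.mean())


def passes_tissue_filter(tile: np.ndarray, min_coverage: float = 0.5, **kw) -> bool:
    """Strict-majority tissue rule: keep a tile iff coverage > ``min_coverage``."""
    return tissue_coverage(tile, **kw) > min_coverage


def split_dataset(
    manifest: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded, disjoint, exhaustive train/val/test split of a manifest.

    Val and test sizes are floored; the remainder goes to train.
    """
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_val = int(np.floor(spec.fractions[1] * n))
    n_test = int(np.floor(spec.fractions[2] * n))
    n_train = n - n_val - n_test
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    return (
        manifest.iloc[idx_train].reset_index(drop=True),
        manifest.iloc[idx_val].reset_index(drop=True),
        manifest.iloc[idx_test].reset_index(drop=True),
    )


def rank_by_stain_variance(tiles: Sequence[np.ndarray]) -> list[int]:
    """Optional ranking of RGB tiles by combined stain-channel variance.

    Tiles rich in both nuclear (hematoxylin) and stromal (eosin) material
    show high variance in the deconvolved stain channels; sorting by the
    summed variance surfaces peritumoral-stroma-like composites.  Returns
    tile indices, most stain-varied first.
    """
    from skimage.color import rgb2hed

    scores = []
    for t in tiles:
        hed = rgb2hed(t.astype(np.float64) / 255.0)
        scores.append(float(hed[..., 0].var() + hed[..., 1].var()))
    return list(np.argsort(scores)[::-1])


def keep_all(_: np.ndarray) -> bool:
    """Default pluggable patch filter: keep every patch."""
    return True
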