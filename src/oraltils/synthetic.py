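"""Seeded generator of histology-like tiles and labelled large-FOV samples.

Real oral-cancer slides cannot ship with the package, so every stage of the
pipeline is exercised on synthetic imagery that mimics the *statistical*
structure of H&E histology: an eosin-pink background, three nucleus
populations (tumour, TILs, stroma) drawn as rotated, boundary-perturbed
ellipses with class-specific colours and controllable pixel fractions, a
rare "others" class so all five labels occur, exact ground-truth masks,
normalized distance maps, and large fields of view composed from tiles
whose TIL-pixel fraction determines one of three infiltration classes
(None-to-Very-Less / Slight / Moderate-to-Marked).

Everything is a pure function of ``(config, seed)``: identical inputs give
bit-identical samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .patches import compute_distance_map

__all__ = [
    "SynthConfig",
    "SynthSample",
    "TIL_CLASS_NAMES",
    "generate_cell_tile",
    "generate_fov_sample",
    "generate_benchmark",
    "generate_benchmark_samples",
    "benchmark_recipe",
    "load_benchmark_sample",
]

TIL_CLASS_NAMES = ("none_to_very_less", "slight", "moderate_to_marked")


def _default_fractions() -> dict[int, float]:
    return {1: 0.12, 2: 0.06, 3: 0.10, 4: 0.01}


def _default_colors() -> dict[int, tuple[int, int, int]]:
    # nucleus base colours: tumour large violet, TILs small dark blue,
    # stroma elongated pale pink-purple, others grey
    return {1: (140, 60, 160), 2: (55, 45, 130), 3: (205, 130, 170), 4: (120, 120, 120)}


@dataclass(frozen=True)
class SynthConfig:
    tile_size: int = 256
    cell_radius_range: tuple[int, int] = (4, 9)
    per_class_target_fraction: dict[int, float] = field(default_factory=_default_fractions)
    background_color: tuple[int, int, int] = (240, 214, 226)
    class_colors: dict[int, tuple[int, int, int]] = field(default_factory=_default_colors)
    class_color_jitter: float = 8.0
    noise_sigma: float = 4.0
    fov_size: int = 4000
    til_band_edges: tuple[float, float] = (0.02, 0.10)
    # complementarity controls (used by the fusion benchmark):
    stripe_amplitude: float = 0.0  # brightness texture visible only in the image
    stripe_period: int = 16
    til_mimics_stroma: bool = False  # draw TIL nuclei with the stroma colour

    def validate(self) -> None:
        total = sum(self.per_class_target_fraction.values())
        if total >= 1.0:
            raise ValueError(
                f"per-class target fractions sum to {total:.3f}; must leave background"
            )
        if any(f < 0 for f in self.per_class_target_fraction.values()):
            raise ValueError("target fractions must be non-negative")
        e1, e2 = self.til_band_edges
        if not (0.0 < e1 < e2 < 1.0):
            raise ValueError("til_band_edges must be strictly increasing within (0,1)")
        if self.cell_radius_range[0] < 1 or self.cell_radius_range[1] < self.cell_radius_range[0]:
            raise ValueError("invalid cell radius range")


@dataclass
class SynthSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, labels 0..4
    distance: np.ndarray  # (H, W) float32 in [0, 1]
    seed: int
    label: int | None = None


def _ellipse_pixels(rng, cls: int, size: int, radius_range) -> tuple[np.ndarray, np.ndarray]:
    """Sample one nucleus and rasterize it; returns (rows, cols) inside tile."""
    r_lo, r_hi = radius_range
    if cls == 2:  # TILs: small, round
        r = rng.uniform(r_lo, max(r_lo + 1, (r_lo + r_hi) / 2))
        a, b = r, r * rng.uniform(0.9, 1.1)
    elif cls == 3:  # stroma: elongated spindles
        r = rng.uniform(r_lo, r_hi)
        a, b = r * rng.uniform(1.6, 2.2), r * rng.uniform(0.45, 0.65)
    else:  # tumour / others: large-ish ellipses
        r = rng.uniform((r_lo + r_hi) / 2, r_hi)
        a, b = r, r * rng.uniform(0.7, 1.0)
    theta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.0, 0.12)  # mild boundary perturbation
    cy, cx = rng.uniform(0, size, 2)
    ext = int(np.ceil(max(a, b) * 1.2)) + 1
    ys = np.arange(int(np.floor(cy)) - ext, int(np.ceil(cy)) + ext + 1)
    xs = np.arange(int(np.floor(cx)) - ext, int(np.ceil(cx)) + ext + 1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v, u)
    inside = rho <= 1.0 + amp * np.sin(3 * phi + phase)
    valid = inside & (yy >= 0) & (yy < size) & (xx >= 0) & (xx < size)
    return yy[valid], xx[valid]


def generate_cell_tile(config: SynthConfig, seed: int) -> SynthSample:
    """Draw one tile of textured elliptical nuclei over background.

    Classes are painted tumour, stroma, others, TILs — later paint wins on
    the rare overlaps — with candidate nuclei that would mostly cover
    existing foreground rejected, so every class's realized pixel fraction
    lands close to its target (the error is bounded by roughly one nucleus
    area per class).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    size = config.tile_size
    mask = np.zeros((size, size), np.uint8)
    image = np.full((size, size, 3), config.background_color, np.float32)
    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, image.shape).astype(np.float32)

    n_pix = size * size
    for cls in (1, 3, 4, 2):  # TILs last: their fraction is the label signal
        target = config.per_class_target_fraction.get(cls, 0.0)
        if target <= 0:
            continue
        painted = int((mask == cls).sum())
        attempts = 0
        max_attempts = 200 + int(40 * target * n_pix)
        while painted < target * n_pix and attempts < max_attempts:
            attempts += 1
            ys, xs = _ellipse_pixels(rng, cls, size, config.cell_radius_range)
            if ys.size == 0:
                continue
            overlap = (mask[ys, xs] > 0).mean()
            if overlap > 0.25 and attempts < max_attempts - 10:
                continue
            mask[ys, xs] = cls
            color_cls = 3 if (cls == 2 and config.til_mimics_stroma) else cls
            base = np.array(config.class_colors[color_cls], np.float32)
            jitter = rng.normal(0.0, config.class_color_jitter, 3).astype(np.float32)
            image[ys, xs] = base + jitter
            if config.noise_sigma > 0:
                image[ys, xs] += rng.normal(0.0, config.noise_sigma, (ys.size, 3)).astype(
                    np.float32
                )
            painted = int((mask == cls).sum())

    if config.stripe_amplitude > 0:
        cols = np.arange(size, dtype=np.float32)
        stripe = 1.0 + config.stripe_amplitude * np.sin(2 * np.pi * cols / config.stripe_period)
        image *= stripe[None, :, None]

    image = np.clip(image, 0, 255).astype(np.uint8)
    distance = compute_distance_map(mask)
    return SynthSample(image=image, mask=mask, distance=distance, seed=seed)


def til_band_targets(config: SynthConfig) -> tuple[float, float, float]:
    """Per-class TIL pixel-fraction targets sitting safely inside each band."""
    e1, e2 = config.til_band_edges
    return (0.3 * e1, 0.5 * (e1 + e2), min(e2 * 1.6, e2 + 0.5 * (1 - e2)))


def classify_til_fraction(fraction: float, band_edges: tuple[float, float]) -> int:
    """Band rule: below first edge -> 0, between -> 1, above second -> 2."""
    e1, e2 = band_edges
    return 0 if fraction < e1 else (1 if fraction < e2 else 2)


def _compose_fov(config: SynthConfig, f_til: float, seed: int, label: int) -> SynthSample:
    """Assemble a FOV from seeded tiles generated at TIL fraction ``f_til``."""
    tile_cfg = replace(
        config,
        per_class_target_fraction={**config.per_class_target_fraction, 2: f_til},
    )
    n = -(-config.fov_size // config.tile_size)  # ceil: generate then crop
    ss = np.random.SeedSequence([seed, label])
    child = np.random.default_rng(ss).integers(0, 2**31 - 1, size=n * n)
    ts = config.tile_size
    image = np.zeros((n * ts, n * ts, 3), np.uint8)
    mask = np.zeros((n * ts, n * ts), np.uint8)
    for i in range(n):
        for j in range(n):
            s = generate_cell_tile(tile_cfg, int(child[i * n + j]))
            image[i * ts : (i + 1) * ts, j * ts : (j + 1) * ts] = s.image
            mask[i * ts : (i + 1) * ts, j * ts : (j + 1) * ts] = s.mask
    image = image[: config.fov_size, : config.fov_size]
    mask = mask[: config.fov_size, : config.fov_size]
    distance = compute_distance_map(mask)
    return SynthSample(image=image, mask=mask, distance=distance, seed=seed, label=label)


def generate_fov_sample(config: SynthConfig, target_class: int, seed: int) -> SynthSample:
    """Compose a large-FOV sample whose TIL fraction falls in the target band."""
    config.validate()
    if target_class not in (0, 1, 2):
        raise ValueError("target_class must be 0, 1 or 2")
    return _compose_fov(config, til_band_targets(config)[target_class], seed, target_class)


def benchmark_recipe(config: SynthConfig, target_class: int) -> tuple[SynthConfig, float]:
    """Per-class complementarity recipe for the fusion benchmark.

    The density cue (TIL pixel fraction: low for class 0, identically high
    for classes 1 and 2) separates class 0 from the rest but not 1 from 2;
    the texture cue (brightness stripes, class 2 only) separates class 2
    but is invisible in the mask.  TIL nuclei are painted in the stroma
    colour and the stroma fraction is padded so the *total* nucleus area
    matches across classes — the raw image therefore carries no density
    cue, and only fusing both modalities resolves all three classes.
    """
    low, _, high = til_band_targets(config)
    f_til = low if target_class == 0 else high
    stroma = config.per_class_target_fraction.get(3, 0.0) + (high - f_til)
    cfg = replace(
        config,
        per_class_target_fraction={**config.per_class_target_fraction, 3: stroma},
        stripe_amplitude=0.25 if target_class == 2 else 0.0,
        til_mimics_stroma=True,
    )
    return cfg, f_til


def generate_benchmark_samples(
    n_per_class: int, config: SynthConfig, seed: int
) -> list[SynthSample]:
    """In-memory version of :func:`generate_benchmark` (same samples)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    config.validate()
    ss = np.random.SeedSequence(seed)
    sample_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, size=3 * n_per_class)
    samples = []
    for cls in range(3):
        cfg, f_til = benchmark_recipe(config, cls)
        for i in range(n_per_class):
            samples.append(_compose_fov(cfg, f_til, int(sample_seeds[cls * n_per_class + i]), cls))
    return samples


def generate_benchmark(
    n_per_class: int, config: SynthConfig, out_dir: str | Path, seed: int
) -> pd.DataFrame:
    """Write a labelled FOV benchmark with a controlled complementarity signal.

    Emits PNG images, masks and 16-bit distance maps plus ``manifest.csv``
    with columns path_image, path_mask, path_distance, label, seed.  Paths
    in the manifest are relative to ``out_dir``.
    """
    samples = generate_benchmark_samples(n_per_class, config, seed)
    out = Path(out_dir)
    for sub in ("images", "masks", "distances"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {0: 0, 1: 0, 2: 0}
    for sample in samples:
        cls = sample.label
        stem = f"class{cls}_{counters[cls]:03d}"
        counters[cls] += 1
        p_img = f"images/{stem}.png"
        p_mask = f"masks/{stem}.png"
        p_dist = f"distances/{stem}.png"
        iio.imwrite(out / p_img, sample.image)
        iio.imwrite(out / p_mask, sample.mask)
        iio.imwrite(out / p_dist, (sample.distance * 65535).round().astype(np.uint16))
        rows.append(
            {
                "path_image": p_img,
                "path_mask": p_mask,
                "path_distance": p_dist,
                "label": cls,
                "seed": sample.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_benchmark_sample(out_dir: str | Path, row: pd.Series) -> SynthSample:
    """Read one manifest row back into arrays (distance rescaled to [0,1])."""
    out = Path(out_dir)
    image = iio.imread(out / row["path_image"])
    mask = iio.imread(out / row["path_mask"])
    distance = iio.imread(out / row["path_distance"]).astype(np.float32) / 65535.0
    return SynthSample(
        image=image, mask=mask, distance=distance, seed=int(row["seed"]), label=int(row["label"])
    )


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
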