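"""Shared fixtures: small synthetic datasets and briefly trained models.

Session scope keeps the expensive artefacts (a trained tiny segmenter)
shared across test modules; everything is seeded so the suite is
deterministic end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from oraltils.segmentation import SegModelConfig, SegTrainConfig, build_tilseg, train_segmentation
from oraltils.synthetic import SynthConfig, generate_cell_tile


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    return SynthConfig(tile_size=64, cell_radius_range=(3, 6))


@pytest.fixture(scope="session")
def seg_tiles(small_synth_config):
    return [generate_cell_tile(small_synth_config, seed) for seed in range(8)]


@pytest.fixture(scope="session")
def untrained_seg_model():
    return build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"), seed=0)


@pytest.fixture(scope="session")
def trained_seg_model(seg_tiles):
    """A micro segmenter fitted briefly on 8 tiles — enough signal for the
    contract tests (confidence gating, density rendering, consistency)."""
    model = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"), seed=1)
    cfg = SegTrainConfig(epochs=80, batch_size=8, learning_rate=0.01, max_steps=80, seed=1)
    model, _ = train_segmentation(model, seg_tiles, cfg)
    return model


@pytest.fixture(scope="session")
def seg_corpus(small_synth_config):
    """200 training tiles plus 20 held-out tiles from the same distribution."""
    train = [generate_cell_tile(small_synth_config, s) for s in range(200)]
    held_out = [generate_cell_tile(small_synth_config, 10_000 + s) for s in range(20)]
    return train, held_out


@pytest.fixture(scope="session")
def seg200_model(seg_corpus):
    """Segmenter given a short full-capacity fit on the 200-tile corpus."""
    train, _ = seg_corpus
    model = build_tilseg(SegModelConfig(input_size=64, encoder_variant="micro"), seed=0)
    cfg = SegTrainConfig(epochs=8, batch_size=8, learning_rate=0.005, seed=0)
    model, _ = train_segmentation(model, train, cfg)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
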