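"""Desk-scale study conditions: small, CPU-trainable synthetic experiments.

These are the fixed reduced-scale counterparts of the full imaging study,
sized so that a complete train/evaluate cycle runs in minutes on one CPU:

* 64 px tiles cut from 640 x 640 synthetic scans (100 tiles per scan);
* cells rendered at ~7 px radius with 8-16 spicules per echinocyte — fewer,
  larger spicules than at full scale so the thorny boundary stays above the
  pixel sampling limit;
* a 1/8-width network (channel_scale 0.125) on 64 px inputs;
* storage classification: echinocyte fractions 0.05 / 0.35 / 0.70 for weeks
  0 / 1 / 2, 300 training and 60 test tiles per class;
* RS regression: five echinocyte levels 0.1 .. 0.9 spanning the RS link
  range, 150 training and 40 test tiles per level.
"""

from __future__ import annotations

import numpy as np

from .nn import CnnSpec
from .synthetic import SmearSimParams, make_labeled_corpus
from .tiling import (
    FilterConfig,
    TileDataset,
    build_dataset,
    filter_empty,
    filter_occluded,
    tile_scan,
)
from .train_eval import TrainConfig

DESK_TILE = 64

DESK_SPEC = CnnSpec(input_size=DESK_TILE, channel_scale=1 / 8)

STORAGE_WEEK_FRACTIONS = {0: 0.05, 1: 0.35, 2: 0.70}
STORAGE_QUOTAS = dict(train_quota=300, test_quota=60, validation_quota=50)
STORAGE_SCANS_PER_CLASS = 5
STORAGE_TRAIN = TrainConfig(epochs=15, learning_rate=0.01)

REGRESSION_LEVEL_FRACTIONS = {0: 0.1, 1: 0.3, 2: 0.5, 3: 0.7, 4: 0.9}
REGRESSION_QUOTAS = dict(train_quota=150, test_quota=40, validation_quota=50)
REGRESSION_SCANS_PER_CLASS = 3  # ~300 raw tiles/level; comfortable filter margin
REGRESSION_TRAIN = TrainConfig(epochs=20, learning_rate=0.005)


def desk_params() -> SmearSimParams:
    return SmearSimParams(
        image_size=(640, 640),
        tile_size=DESK_TILE,
        cells_per_tile=8.0,
        cell_radius_mean=7.0,
        cell_radius_sd=1.0,
        spicule_amplitude=0.25,
        spicule_count_range=(8, 16),
    )


def build_corpus_dataset(
    week_fractions: dict[int, float],
    n_scans_per_class: int,
    seed: int,
    train_quota: int,
    test_quota: int,
    validation_quota: int = 50,
) -> tuple[TileDataset, dict]:
    """Render a corpus, tile + filter it, and assemble the split dataset.

    Returns the dataset plus a ``(scan_id, row, col) -> boolean mask`` map of
    ground-truth cell coverage for saliency scoring.
    """
    rng = np.random.default_rng(seed)
    base = desk_params()
    samples, _ = make_labeled_corpus(
        rng,
        week_fractions=week_fractions,
        n_scans_per_class=n_scans_per_class,
        base_params=base,
    )
    fcfg = FilterConfig(
        background_reference=base.background_level, empty_tolerance=0.015
    )
    tiles_by_class: dict[int, list] = {}
    masks: dict[tuple, np.ndarray] = {}
    s_px = DESK_TILE
    for s in samples:
        tiles = tile_scan(s.scan, tile_size=s_px)
        for t in tiles:
            t.rs = s.rs
            t.bin_index = s.bin_index
            masks[(t.scan_id, t.row, t.col)] = s.truth.mask[
                t.row * s_px : (t.row + 1) * s_px, t.col * s_px : (t.col + 1) * s_px
            ]
        kept = filter_occluded(filter_empty(tiles, fcfg), fcfg)
        tiles_by_class.setdefault(s.scan.storage_week, []).extend(kept)
    dataset = build_dataset(
        tiles_by_class,
        seed=seed + 1,
        train_quota=train_quota,
        test_quota=test_quota,
        validation_quota=validation_quota,
    )
    return dataset, masks
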