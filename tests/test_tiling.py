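"""Tiling, filtering, dataset splits, augmentation."""

import numpy as np
import pytest

from rbcsmear.synthetic import SmearSimParams, render_scan
from rbcsmear.tiling import (
    ConfigurationError,
    FilterConfig,
    ShortfallError,
    SmearScan,
    Tile,
    augment,
    build_dataset,
    filter_empty,
    filter_occluded,
    tile_scan,
)


def make_scan(h, w, value=0.5, scan_id="s"):
    return SmearScan(
        pixels=np.full((h, w), value, dtype=np.float32),
        donor_id="d", storage_week=0, scan_id=scan_id,
    )


class TestTileScan:
    @pytest.mark.parametrize(
        "h, w, tile, expected",
        [
            (2424, 2424, 256, 81),  # the reference scan geometry: 9 x 9
            (256, 256, 256, 1),
            (512, 300, 256, 2),
            (640, 640, 64, 100),
        ],
    )
    def test_tile_counts(self, h, w, tile, expected):
        tiles = tile_scan(make_scan(h, w), tile_size=tile)
        assert len(tiles) == expected
        assert len(tiles) == (h // tile) * (w // tile)

    def test_tiles_disjoint_and_anchored(self):
        tiles = tile_scan(make_scan(300, 550), tile_size=128)
        seen = set()
        for t in tiles:
            assert t.pixels.shape == (128, 128)
            assert (t.row, t.col) not in seen
            seen.add((t.row, t.col))
        assert {(t.row, t.col) for t in tiles} == {(r, c) for r in range(2) for c in range(4)}

    def test_scan_smaller_than_tile_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            tile_scan(make_scan(100, 300), tile_size=256)

    def test_multichannel_converted_to_grayscale(self):
        scan = SmearScan(pixels=np.zeros((256, 256, 3), dtype=np.float32),
                         donor_id="d", storage_week=0, scan_id="rgb")
        tiles = tile_scan(scan)
        assert tiles[0].pixels.ndim == 2


class TestFilters:
    def cfg(self, **kw):
        defaults = dict(background_reference=0.85, empty_tolerance=0.02,
                        occlusion_max_blob_fraction=0.25)
        defaults.update(kw)
        return FilterConfig(**defaults)

    def tile_of(self, pixels):
        return Tile(pixels=np.asarray(pixels, dtype=np.float32),
                    scan_id="s", row=0, col=0)

    def test_uniform_background_tile_removed(self):
        t = self.tile_of(np.full((64, 64), 0.85))
        assert filter_empty([t], self.cfg()) == []

    def test_tile_with_cells_kept(self):
        params = SmearSimParams(image_size=(64, 64), tile_size=64, cells_per_tile=4,
                                cell_radius_mean=7, noise_sd=0.0, background_jitter=0.0)
        for seed in range(5):
            scan, truth = render_scan(params, np.random.default_rng(seed))
            if len(truth.cells) >= 3:
                t = self.tile_of(scan.pixels)
                assert filter_empty([t], self.cfg()) == [t]

    def test_all_empty_scan_yields_nothing(self):
        params = SmearSimParams(image_size=(128, 128), tile_size=64, cells_per_tile=0,
                                noise_sd=0.001, background_jitter=0.0)
        scan, truth = render_scan(params, np.random.default_rng(0))
        assert truth.cells.empty
        tiles = tile_scan(scan, tile_size=64)
        assert filter_empty(tiles, self.cfg()) == []

    def test_uncalibrated_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_empty([], FilterConfig())

    def test_large_blob_removed(self):
        pixels = np.full((64, 64), 0.85, dtype=np.float32)
        pixels[:41, :41] = 0.2  # one dark blob covering 40% of the area
        t = self.tile_of(pixels)
        assert filter_occluded([t], self.cfg(foreground_threshold=0.5)) == []

    def test_separated_cells_kept(self):
        params = SmearSimParams(image_size=(64, 64), tile_size=64, cells_per_tile=4,
                                cell_radius_mean=6, overlap_rate=0.0)
        scan, truth = render_scan(params, np.random.default_rng(3))
        t = self.tile_of(scan.pixels)
        # each rendered cell covers < 5% of tile area
        assert (np.pi * truth.cells.radius.max() ** 2) / (64 * 64) < 0.05
        assert filter_occluded([t], self.cfg(foreground_threshold=0.6)) == [t]

    def test_blank_tile_passes_occlusion_filter(self):
        t = self.tile_of(np.full((64, 64), 0.85))
        assert filter_occluded([t], self.cfg(foreground_threshold=0.5)) == [t]

    def test_filters_order_stable(self):
        params = SmearSimParams(image_size=(320, 320), tile_size=64, cells_per_tile=3)
        scan, _ = render_scan(params, np.random.default_rng(5))
        tiles = tile_scan(scan, tile_size=64)
        cfg = self.cfg()
        a = filter_occluded(filter_empty(tiles, cfg), cfg)
        b = filter_empty(filter_occluded(tiles, cfg), cfg)
        assert [t.provenance for t in a] == [t.provenance for t in b]


class TestAugment:
    def test_identity_path(self):
        tile = np.random.default_rng(0).random((32, 32)).astype(np.float32)

        class FixedRng:
            def integers(self, *a, **k):
                return 0

            def random(self):
                return 0.9  # no flip

        out = augment(tile, FixedRng())
        np.testing.assert_array_equal(out, tile)

    def test_four_rotations_return_original(self):
        tile = np.random.default_rng(1).random((16, 16)).astype(np.float32)
        out = tile
        for _ in range(4):
            out = np.rot90(out, 1)
        np.testing.assert_array_equal(out, tile)

    def test_histogram_preserved(self):
        """Rotations/flips permute pixels; the intensity multiset is invariant."""
        tile = np.random.default_rng(2).random((64, 64)).astype(np.float32)
        rng = np.random.default_rng(3)
        for _ in range(10):
            out = augment(tile, rng)
            np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(tile.ravel()))

    def test_normalization_applied_last(self):
        tile = np.full((8, 8), 2.0, dtype=np.float32)
        rng = np.random.default_rng(0)
        out = augment(tile, rng, mean=2.0, std=4.0)
        np.testing.assert_allclose(out, 0.0)


def tiles_for(n, cls):
    rng = np.random.default_rng(hash(cls) % 2**31)
    return [
        Tile(pixels=rng.random((8, 8)).astype(np.float32), scan_id=f"{cls}_{i // 10}",
             row=i % 10, col=0)
        for i in range(n)
    ]


class TestBuildDataset:
    def test_quota_satisfied_and_disjoint(self):
        pools = {"a": tiles_for(200, "a"), "b": tiles_for(200, "b")}
        ds = build_dataset(pools, seed=0, train_quota=100, test_quota=40,
                           validation_quota=50, n_folds=5)
        for cls in ("a", "b"):
            rows = ds.manifest[ds.manifest.class_label == cls]
            assert (rows.split == "train").sum() == 100
            assert (rows.split == "test").sum() == 40
            train_ids = set(rows[rows.split == "train"].tile_index)
            test_ids = set(rows[rows.split == "test"].tile_index)
            assert not train_ids & test_ids
            folds = rows[rows.fold >= 0]
            assert len(folds) == 50
            assert sorted(folds.fold.unique()) == [0, 1, 2, 3, 4]
            assert (folds.fold.value_counts() == 10).all()
            assert (folds.split == "train").all()

    def test_same_seed_identical_membership(self):
        pools = {"a": tiles_for(120, "a")}
        d1 = build_dataset(pools, seed=9, train_quota=80, test_quota=20,
                           validation_quota=20, n_folds=5)
        d2 = build_dataset(pools, seed=9, train_quota=80, test_quota=20,
                           validation_quota=20, n_folds=5)
        assert d1.manifest.equals(d2.manifest)

    def test_shortfall_error_lists_class(self):
        pools = {"a": tiles_for(50, "a")}
        with pytest.raises(ShortfallError, match="'a'"):
            build_dataset(pools, seed=0, train_quota=100, test_quota=20,
                          validation_quota=20)

    def test_normalization_stats_from_training_split_only(self):
        pools = {"a": tiles_for(100, "a")}
        ds = build_dataset(pools, seed=1, train_quota=60, test_quota=20,
                           validation_quota=20, n_folds=5)
        x_train, _ = ds.split_arrays("train")
        assert ds.norm_mean == pytest.approx(float(x_train.mean()))
        # optical-density convention: stained (dark) pixels map to positive values
        dark = np.zeros((1, 1, 8, 8), dtype=np.float32)
        assert ds.normalize(dark).mean() > 0
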