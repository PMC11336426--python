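"""Tile extraction, filtering, splitting and augmentation for smear scans.

Large brightfield scans of Giemsa-stained thin-film smears (reference
acquisition: 2424 x 2424 px, 14-bit) are cut into non-overlapping grayscale
tiles (default 256 x 256).  Tiles are deliberately multi-cell: no single-cell
segmentation is attempted.  Empty tiles are dropped by comparing their mean
intensity against a cell-free background reference; tiles dominated by one
large clump of overlapping cells are dropped by a largest-connected-component
criterion.  Surviving tiles are subsampled into train/test splits with a
cross-validation fold structure, and augmented by right-angle rotation and
horizontal flipping.

Intensities are handled as floating point in [0, 1]; scans carry their native
bit depth as metadata and are written to disk in 16-bit containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

DEFAULT_TILE_SIZE = 256


class ConfigurationError(ValueError):
    """A filter or dataset configuration is incomplete or inconsistent."""


class ShortfallError(ValueError):
    """Requested split quotas exceed the available tiles."""


@dataclass
class SmearScan:
    """A single large smear image with provenance.

    ``pixels`` is a 2-D (grayscale) or 3-D (multichannel) float array scaled
    to [0, 1]; ``bit_depth`` records the native acquisition depth.
    """

    pixels: np.ndarray
    donor_id: str
    storage_week: int
    scan_id: str
    bit_depth: int = 14

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)


@dataclass
class Tile:
    """A tile_size x tile_size grayscale patch with provenance and labels."""

    pixels: np.ndarray
    scan_id: str
    row: int
    col: int
    donor_id: str = ""
    storage_week: int = 0
    rs: float | None = None
    bin_index: int | None = None

    @property
    def provenance(self) -> tuple[str, int, int]:
        return (self.scan_id, self.row, self.col)


@dataclass
class FilterConfig:
    """Parameters for the empty-tile and occluded-tile filters.

    background_reference:
        Mean intensity of a cell-free image (same illumination); must be
        calibrated before ``filter_empty`` runs.
    empty_tolerance:
        Relative deviation of a tile's mean from the background below which
        the tile is considered cell-free.
    occlusion_max_blob_fraction:
        Maximum tolerated area fraction of the largest foreground connected
        component; a bigger blob indicates clumped or overlapping cells.
    foreground_threshold:
        Intensity below which a pixel counts as stained foreground (cells are
        darker than background).  ``None`` selects a per-tile Otsu threshold.
    """

    background_reference: float | None = None
    empty_tolerance: float = 0.02
    occlusion_max_blob_fraction: float = 0.25
    foreground_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.empty_tolerance < 1.0):
            raise ConfigurationError("empty_tolerance must lie in (0, 1)")
        if not (0.0 < self.occlusion_max_blob_fraction < 1.0):
            raise ConfigurationError("occlusion_max_blob_fraction must lie in (0, 1)")


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse a trailing channel axis by averaging; pass 2-D through."""
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim == 3:
        return pixels.mean(axis=-1)
    if pixels.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got shape {pixels.shape}")
    return pixels


def tile_scan(scan: SmearScan, tile_size: int = DEFAULT_TILE_SIZE) -> list[Tile]:
    """Cut a scan into floor(H/s) x floor(W/s) non-overlapping tiles.

    The grid is anchored at the top-left corner; any right/bottom remainder
    narrower than ``tile_size`` is discarded (a 2424 px scan at 256 px tiles
    yields a 9 x 9 grid with a 120 px margin dropped on each axis).
    """
    pixels = to_grayscale(scan.pixels)
    h, w = pixels.shape
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"scan {scan.scan_id} ({h}x{w}) smaller than tile size {tile_size}"
        )
    n_rows, n_cols = h // tile_size, w // tile_size
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            patch = pixels[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
            ]
            tiles.append(
                Tile(
                    pixels=patch,
                    scan_id=scan.scan_id,
                    row=r,
                    col=c,
                    donor_id=scan.donor_id,
                    storage_week=scan.storage_week,
                )
            )
    return tiles


def filter_empty(tiles: Sequence[Tile], cfg: FilterConfig) -> list[Tile]:
    """Drop tiles whose mean intensity sits within tolerance of background."""
    if cfg.background_reference is None:
        raise ConfigurationError(
            "background_reference must be calibrated from a cell-free image"
        )
    bg = float(cfg.background_reference)
    kept = []
    for tile in tiles:
        deviation = abs(float(tile.pixels.mean()) - bg) / bg
        if deviation >= cfg.empty_tolerance:
            kept.append(tile)
    return kept


def _foreground_mask(pixels: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    if cfg.foreground_threshold is not None:
        thresh = cfg.foreground_threshold
    else:
        if np.ptp(pixels) == 0:
            return np.zeros(pixels.shape, dtype=bool)
        thresh = threshold_otsu(pixels)
    return pixels < thresh  # stained cells are darker than background


def filter_occluded(tiles: Sequence[Tile], cfg: FilterConfig) -> list[Tile]:
    """Drop tiles whose largest foreground component dominates the tile.

    A single connected component covering more than
    ``occlusion_max_blob_fraction`` of the tile area is taken as evidence of
    substantial cell overlap/clumping.  Tiles with no foreground at all pass
    this filter (they are the empty filter's responsibility).
    """
    kept = []
    for tile in tiles:
        fg = _foreground_mask(tile.pixels, cfg)
        if not fg.any():
            kept.append(tile)
            continue
        components = cc_label(fg, connectivity=2)
        largest = np.bincount(components.ravel())[1:].max()
        if largest / fg.size <= cfg.occlusion_max_blob_fraction:
            kept.append(tile)
    return kept


def augment(
    tile: np.ndarray,
    rng: np.random.Generator,
    mean: float | None = None,
    std: float | None = None,
) -> np.ndarray:
    """Grayscale -> k*90-degree rotation -> random horizontal flip -> normalize.

    Rotation count k is uniform on {0, 1, 2, 3}; the flip fires with
    probability 1/2.  If ``mean``/``std`` are given the result is
    standardized, otherwise intensities pass through unchanged.
    """
    out = to_grayscale(tile)
    k = int(rng.integers(0, 4))
    out = np.rot90(out, k)
    if rng.random() < 0.5:
        out = np.fliplr(out)
    if mean is not None and std is not None:
        out = (out - mean) / std
    return np.ascontiguousarray(out)


def augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent rot90/flip augmentation of an (N, 1, H, W) batch."""
    out = np.empty_like(batch)
    for i in range(batch.shape[0]):
        img = np.rot90(batch[i, 0], int(rng.integers(0, 4)))
        if rng.random() < 0.5:
            img = np.fliplr(img)
        out[i, 0] = img
    return out


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

#: Reference split sizes: 10,000 training and 2,000 testing tiles per class,
#: with 2,000 training tiles rotated through 5 validation folds.
REFERENCE_SCALE_QUOTAS = {"train": 10_000, "test": 2_000, "validation": 2_000}


@dataclass
class TileDataset:
    """Filtered tiles organised into train/test splits with CV folds.

    ``manifest`` has one row per selected tile with columns
    (class_label, scan_id, donor_id, storage_week, row, col, rs, bin_index,
    split, fold); ``fold`` is -1 outside the validation pool.  ``norm_mean``
    and ``norm_std`` are computed on the training split only.
    """

    tiles: dict[object, list[Tile]]
    manifest: pd.DataFrame
    split_seed: int
    n_folds: int = 5
    norm_mean: float = 0.0
    norm_std: float = 1.0
    augmentation: bool = True

    def _select(self, class_label: object, mask: np.ndarray) -> np.ndarray:
        rows = self.manifest[self.manifest["class_label"] == class_label]
        chosen = rows[mask(rows)]
        stack = np.stack(
            [self.tiles[class_label][i].pixels for i in chosen["tile_index"]]
        )
        return stack[:, None, :, :]  # NCHW

    def split_arrays(
        self, split: str, exclude_fold: int | None = None, only_fold: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (X, y) for a split; y is the integer class index.

        ``exclude_fold`` removes one validation fold from the training split;
        ``only_fold`` selects exactly that fold.
        """
        classes = sorted(self.tiles.keys(), key=str)
        xs, ys = [], []
        for idx, cls in enumerate(classes):
            def mask(rows):
                m = rows["split"] == split
                if exclude_fold is not None:
                    m &= rows["fold"] != exclude_fold
                if only_fold is not None:
                    m &= rows["fold"] == only_fold
                return m

            x = self._select(cls, mask)
            xs.append(x)
            ys.append(np.full(len(x), idx, dtype=np.int64))
        return np.concatenate(xs), np.concatenate(ys)

    def regression_arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (X, rs) for regression; requires rs labels on every tile."""
        xs, ys = [], []
        for cls in sorted(self.tiles.keys(), key=str):
            rows = self.manifest[
                (self.manifest["class_label"] == cls) & (self.manifest["split"] == split)
            ]
            if rows["rs"].isna().any():
                raise ConfigurationError("regression requires rs labels on all tiles")
            xs.append(
                np.stack([self.tiles[cls][i].pixels for i in rows["tile_index"]])[
                    :, None, :, :
                ]
            )
            ys.append(rows["rs"].to_numpy(dtype=np.float32))
        return np.concatenate(xs), np.concatenate(ys)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Standardized optical density, fitted on the training split.

        Brightfield intensities are inverted (mean-minus-intensity) before
        scaling, so stained cells carry positive signal and background sits
        near zero — the representation the network consumes.
        """
        return (self.norm_mean - x) / self.norm_std

    @property
    def class_labels(self) -> list[object]:
        return sorted(self.tiles.keys(), key=str)


def build_dataset(
    tiles_by_class: Mapping[object, Sequence[Tile]],
    seed: int,
    train_quota: int = REFERENCE_SCALE_QUOTAS["train"],
    test_quota: int = REFERENCE_SCALE_QUOTAS["test"],
    validation_quota: int = REFERENCE_SCALE_QUOTAS["validation"],
    n_folds: int = 5,
    augmentation: bool = True,
) -> TileDataset:
    """Subsample per-class tile pools into a reproducible split structure.

    Per class: ``test_quota`` tiles are drawn uniformly at random for the
    test split and ``train_quota`` for the training split (disjoint by
    construction); ``validation_quota`` of the training tiles are then
    partitioned into ``n_folds`` equal validation folds.  All randomness
    derives from ``seed``.
    """
    if validation_quota > train_quota:
        raise ConfigurationError("validation_quota cannot exceed train_quota")
    if validation_quota % n_folds != 0:
        raise ConfigurationError("validation_quota must divide evenly into folds")
    rng = np.random.default_rng(seed)
    shortfalls = {
        cls: len(pool)
        for cls, pool in tiles_by_class.items()
        if len(pool) < train_quota + test_quota
    }
    if shortfalls:
        need = train_quota + test_quota
        detail = ", ".join(f"{cls!r}: {n} < {need}" for cls, n in sorted(shortfalls.items(), key=lambda kv: str(kv[0])))
        raise ShortfallError(f"insufficient tiles for requested quotas ({detail})")

    rows = []
    tiles: dict[object, list[Tile]] = {}
    for cls in sorted(tiles_by_class.keys(), key=str):
        pool = list(tiles_by_class[cls])
        tiles[cls] = pool
        order = rng.permutation(len(pool))
        test_idx = order[:test_quota]
        train_idx = order[test_quota : test_quota + train_quota]
        fold_of = {}
        val_idx = rng.permutation(train_idx)[:validation_quota]
        for j, i in enumerate(val_idx):
            fold_of[int(i)] = j % n_folds
        for split, idxs in (("test", test_idx), ("train", train_idx)):
            for i in idxs:
                t = pool[int(i)]
                rows.append(
                    {
                        "class_label": cls,
                        "tile_index": int(i),
                        "scan_id": t.scan_id,
                        "donor_id": t.donor_id,
                        "storage_week": t.storage_week,
                        "row": t.row,
                        "col": t.col,
                        "rs": t.rs,
                        "bin_index": t.bin_index,
                        "split": split,
                        "fold": fold_of.get(int(i), -1),
                    }
                )
    manifest = pd.DataFrame(rows)
    dataset = TileDataset(
        tiles=tiles,
        manifest=manifest,
        split_seed=seed,
        n_folds=n_folds,
        augmentation=augmentation,
    )
    x_train, _ = dataset.split_arrays("train")
    dataset.norm_mean = float(x_train.mean())
    std = float(x_train.std())
    if std == 0:
        warnings.warn("training split has zero intensity variance; std set to 1")
        std = 1.0
    dataset.norm_std = std
    return dataset


def write_manifest(dataset: TileDataset, path: str | Path) -> None:
    dataset.manifest.to_csv(path, index=False)
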