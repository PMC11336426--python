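"""End-to-end reproducible runs: simulate -> score -> tile -> train -> report.

A :class:`RunConfig` captures every knob of every stage plus one global seed;
its SHA-256 hash is stamped into every artifact so each output file is
attributable to exactly one configuration.  The global seed is expanded into
independent per-stage substreams (simulation, sorting, dataset split,
training) so stages can be re-run in isolation while remaining reproducible.

Stage order mirrors the experimental workflow: simulate smears and sorting
distributions -> compute rigidity scores and bins -> tile and filter scans ->
build the split dataset -> train the CNN -> evaluate -> saliency maps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import rigidity
from .nn import CnnSpec, build_model
from .saliency import cell_concentration_score, compute_saliency, overlay, save_map
from .synthetic import (
    DEFAULT_WEEK_ECHINOCYTE_FRACTIONS,
    SmearSimParams,
    SortSimParams,
    make_labeled_corpus,
    simulate_outlet_distribution,
)
from .tiling import (
    FilterConfig,
    build_dataset,
    filter_empty,
    filter_occluded,
    tile_scan,
)
from .train_eval import (
    TrainConfig,
    evaluate_classification,
    evaluate_regression,
    train,
)

log = logging.getLogger("rbcsmear.pipeline")


class ConfigError(ValueError):
    """Unknown or inconsistent run-configuration keys."""


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run.

    The defaults describe a desk-scale synthetic run (64 px tiles,
    1/8-width network) that completes on a single CPU in minutes.
    """

    seed: int = 0
    out_dir: str = "runs/latest"
    task: str = "storage-3"

    # simulator
    image_size: tuple[int, int] = (640, 640)
    tile_size: int = 64
    cells_per_tile: float = 8.0
    cell_radius_mean: float = 7.0
    cell_radius_sd: float = 1.0
    spicule_amplitude: float = 0.25
    spicule_count_range: tuple[int, int] = (8, 16)
    week_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_WEEK_ECHINOCYTE_FRACTIONS)
    )
    n_scans_per_class: int = 5
    sort_sigma: float = 0.6
    sort_n_cells: int = 10_000

    # tiling / dataset
    empty_tolerance: float = 0.015
    occlusion_max_blob_fraction: float = 0.25
    train_quota: int = 300
    test_quota: int = 60
    validation_quota: int = 50
    n_folds: int = 5

    # model / training
    channel_scale: float = 0.125
    fc_widths: tuple[int, ...] = (512, 128)
    learning_rate: float = 0.01
    epochs: int = 15
    batch_size: int = 32

    # saliency
    n_saliency_tiles: int = 4

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("image_size", "spicule_count_range", "fc_widths"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.week_fractions = {int(k): float(v) for k, v in cfg.week_fractions.items()}
        return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "sorting", "split", "model", "train"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict written to the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _stage_seeds(config.seed)
    (out / "config.json").write_text(
        json.dumps({"config": asdict(config), "hash": chash}, indent=2, default=str)
    )
    t_start = time.time()

    # -- simulate ----------------------------------------------------------
    rng_sim = np.random.default_rng(seeds["simulate"])
    base = SmearSimParams(
        image_size=config.image_size,
        tile_size=config.tile_size,
        cells_per_tile=config.cells_per_tile,
        cell_radius_mean=config.cell_radius_mean,
        cell_radius_sd=config.cell_radius_sd,
        spicule_amplitude=config.spicule_amplitude,
        spicule_count_range=config.spicule_count_range,
    )
    samples, scan_manifest = make_labeled_corpus(
        rng_sim,
        week_fractions=config.week_fractions,
        n_scans_per_class=config.n_scans_per_class,
        base_params=base,
    )
    log.info("simulate: %d scans rendered", len(samples))

    # -- rigidity scores from simulated sorting ---------------------------
    rng_sort = np.random.default_rng(seeds["sorting"])
    dists = []
    for week, p_e in sorted(config.week_fractions.items()):
        from .synthetic import rs_link

        dists.append(
            simulate_outlet_distribution(
                SortSimParams(mu=rs_link(p_e), sigma=config.sort_sigma,
                              n_cells=config.sort_n_cells),
                rng_sort,
                donor_id="synthetic",
                storage_week=week,
            )
        )
    rs_table = rigidity.score_table(dists)
    rs_table["config_hash"] = chash
    rs_table.to_csv(out / "rs_table.csv", index=False)
    log.info("rigidity: %d sorting distributions scored", len(dists))

    # -- tile + filter -----------------------------------------------------
    fcfg = FilterConfig(
        background_reference=base.background_level,
        empty_tolerance=config.empty_tolerance,
        occlusion_max_blob_fraction=config.occlusion_max_blob_fraction,
    )
    tiles_by_class: dict[int, list] = {}
    masks = {}
    counts = {"raw": 0, "after_empty": 0, "after_occlusion": 0}
    ts = config.tile_size
    for s in samples:
        tiles = tile_scan(s.scan, tile_size=ts)
        counts["raw"] += len(tiles)
        for t in tiles:
            t.rs = s.rs
            t.bin_index = s.bin_index
            masks[(t.scan_id, t.row, t.col)] = s.truth.mask[
                t.row * ts : (t.row + 1) * ts, t.col * ts : (t.col + 1) * ts
            ]
        kept = filter_empty(tiles, fcfg)
        counts["after_empty"] += len(kept)
        kept = filter_occluded(kept, fcfg)
        counts["after_occlusion"] += len(kept)
        tiles_by_class.setdefault(s.scan.storage_week, []).extend(kept)
    log.info("tiling: %s", counts)

    # -- dataset -----------------------------------------------------------
    dataset = build_dataset(
        tiles_by_class,
        seed=seeds["split"],
        train_quota=config.train_quota,
        test_quota=config.test_quota,
        validation_quota=config.validation_quota,
        n_folds=config.n_folds,
    )
    manifest = dataset.manifest.copy()
    manifest["config_hash"] = chash
    manifest.to_csv(out / "tile_manifest.csv", index=False)

    # -- train -------------------------------------------------------------
    spec = CnnSpec(
        input_size=config.tile_size,
        channel_scale=config.channel_scale,
        fc_widths=config.fc_widths,
    )
    model = build_model(spec, config.task, seed=seeds["model"])
    tcfg = TrainConfig(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=seeds["train"],
    )
    if config.task == "regression":
        x_tr, y_tr = dataset.regression_arrays("train")
        x_te, y_te = dataset.regression_arrays("test")
    else:
        x_tr, y_tr = dataset.split_arrays("train")
        x_te, y_te = dataset.split_arrays("test")
    norm = dataset.normalize
    history = train(model, norm(x_tr), y_tr, tcfg)
    model.save(out / "model.npz")

    # -- evaluate ----------------------------------------------------------
    if config.task == "regression":
        report = evaluate_regression(model, norm(x_te), y_te)
    else:
        report = evaluate_classification(model, norm(x_te), y_te)
    log.info("evaluate: %s", {k: v for k, v in report.to_dict().items() if np.isscalar(v)})

    # -- saliency ----------------------------------------------------------
    sal_dir = out / "saliency"
    sal_dir.mkdir(exist_ok=True)
    concentration = []
    test_rows = dataset.manifest[dataset.manifest.split == "test"].head(
        config.n_saliency_tiles
    )
    import imageio.v3 as iio

    for _, row in test_rows.iterrows():
        tile = dataset.tiles[row.class_label][row.tile_index]
        smap = compute_saliency(model, norm(tile.pixels))
        smap.provenance = (row.scan_id, row.row, row.col)
        name = f"{row.scan_id}_r{row.row}c{row.col}"
        save_map(smap, sal_dir / f"{name}_map.png")
        iio.imwrite(sal_dir / f"{name}_overlay.png", overlay(smap, tile.pixels))
        mask = masks[(row.scan_id, row.row, row.col)]
        concentration.append(cell_concentration_score(smap, mask))

    result = {
        "config_hash": chash,
        "seeds": seeds,
        "tile_counts": counts,
        "rs_table": rs_table.drop(columns="config_hash").to_dict(orient="records"),
        "history": history,
        "evaluation": report.to_dict(),
        "saliency_concentration_mean": float(np.mean(concentration))
        if concentration
        else None,
        "runtime_s": round(time.time() - t_start, 1),
    }
    (out / "report.json").write_text(json.dumps(result, indent=2, default=str))
    return result
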