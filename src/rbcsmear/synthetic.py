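"""Synthetic Giemsa-like smear scans and microfluidic sorting distributions.

Real smear/sorting data for the donor cohort is not publicly deposited, so
this module provides a fully controlled stand-in with pixel-accurate ground
truth.  Two cell morphologies are rendered in grayscale:

* **discocyte** — a disc with a radially symmetric central pallor, the normal
  biconcave red-cell appearance in a stained smear;
* **echinocyte** — a spiculated cell whose boundary radius is modulated as
  ``r(theta) = r0 * (1 + a * cos(k * theta))`` with ``k`` evenly spaced
  thorny projections and a reduced pallor.  Echinocytes are more rigid and
  become more frequent with cold storage, which is the morphological signal
  the imaging pipeline learns.

The sorting simulator draws a latent per-cell rigidity from a normal
distribution and discretizes it into the twelve device outlets via
``outlet = clamp(ceil(latent), 1, 12)``, producing outlet count tables that
feed the rigidity-score machinery.

Storage week is linked to echinocyte fraction (defaults 0.05 / 0.35 / 0.70
for weeks 0/1/2) and continuous rigidity labels follow the monotone link
``rs = 2.30 + 1.26 * p_e``, spanning the observed RS range 2.30-3.56.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .rigidity import N_OUTLETS, OutletDistribution, assign_bin
from .tiling import SmearScan

#: Default storage-week -> echinocyte-fraction link (weeks 0, 1, 2).
DEFAULT_WEEK_ECHINOCYTE_FRACTIONS = {0: 0.05, 1: 0.35, 2: 0.70}

#: Observed rigidity-score span used by the p_e -> RS link.
RS_LINK_RANGE = (2.30, 3.56)


def rs_link(echinocyte_fraction: float) -> float:
    """Monotone, noiseless link from echinocyte fraction to rigidity score."""
    lo, hi = RS_LINK_RANGE
    return lo + (hi - lo) * float(echinocyte_fraction)


class SaturationError(RuntimeError):
    """Cell placement failed: requested density incompatible with overlap limit."""


@dataclass
class SmearSimParams:
    """Knobs of the synthetic smear renderer.

    Intensities are on a [0, 1] scale (bright background, dark stained
    cells); geometric quantities are in pixels.
    """

    image_size: tuple[int, int] = (2424, 2424)
    tile_size: int = 256  # density accounting unit
    cells_per_tile: float = 6.0
    cell_radius_mean: float = 14.0
    cell_radius_sd: float = 1.5
    echinocyte_fraction: float = 0.05
    spicule_count_range: tuple[int, int] = (10, 30)
    spicule_amplitude: float = 0.16
    central_pallor: float = 0.6
    stain_mean: float = 0.55
    stain_sd: float = 0.08
    background_level: float = 0.85
    background_jitter: float = 0.02  # per-scan illumination variation (sd)
    noise_sd: float = 0.02
    overlap_rate: float = 0.05
    max_placement_attempts: int = 60

    def __post_init__(self) -> None:
        for name in ("echinocyte_fraction", "central_pallor", "overlap_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cells_per_tile < 0:
            raise ValueError("cells_per_tile must be non-negative")
        if self.cell_radius_mean <= 0:
            raise ValueError("cell radius must be positive")


@dataclass
class SortSimParams:
    """Latent-rigidity model for the sorting simulator."""

    mu: float
    sigma: float
    n_cells: int

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < N_OUTLETS):
            raise ValueError(f"mu must lie in (0, 12), got {self.mu}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


@dataclass
class GroundTruth:
    """Pixel-accurate ground truth accompanying a rendered scan."""

    cells: pd.DataFrame  # columns: cx, cy, radius, cell_type
    mask: np.ndarray  # boolean cell-coverage mask, same shape as the scan

    def tile_counts(self, tile_size: int) -> pd.DataFrame:
        """Per-tile occupancy and echinocyte counts on the tiling grid."""
        h, w = self.mask.shape
        rows = []
        for r in range(h // tile_size):
            for c in range(w // tile_size):
                y0, y1 = r * tile_size, (r + 1) * tile_size
                x0, x1 = c * tile_size, (c + 1) * tile_size
                inside = self.cells[
                    (self.cells.cy >= y0) & (self.cells.cy < y1)
                    & (self.cells.cx >= x0) & (self.cells.cx < x1)
                ]
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "n_cells": len(inside),
                        "n_echinocytes": int((inside.cell_type == "echinocyte").sum()),
                    }
                )
        return pd.DataFrame(rows)


def render_cell(
    cell_type: str,
    params: SmearSimParams,
    rng: np.random.Generator,
    radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell sprite (absorbance map) and its boolean mask.

    Discocytes are discs with a central pallor; echinocytes modulate the
    boundary radius with a single cosine mode of ``k`` spicules and show a
    reduced pallor.  The sprite holds non-negative absorbance subtracted from
    the bright background at composition time.
    """
    if radius is None:
        radius = float(
            np.clip(rng.normal(params.cell_radius_mean, params.cell_radius_sd), 4.0, None)
        )
    if radius <= 0:
        raise ValueError("cell radius must be positive")
    if cell_type not in ("discocyte", "echinocyte"):
        raise ValueError(f"unknown cell type {cell_type!r}")

    amplitude = params.spicule_amplitude if cell_type == "echinocyte" else 0.0
    k_spicules = (
        int(rng.integers(params.spicule_count_range[0], params.spicule_count_range[1] + 1))
        if cell_type == "echinocyte"
        else 0
    )
    pallor = params.central_pallor * (0.25 if cell_type == "echinocyte" else 1.0)
    stain = float(np.clip(rng.normal(params.stain_mean, params.stain_sd), 0.1, 1.0))
    phase = rng.uniform(0, 2 * math.pi)

    half = int(math.ceil(radius * (1 + amplitude))) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float32)
    rr = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    boundary = radius * (1.0 + amplitude * np.cos(k_spicules * theta + phase))
    # 1 px soft edge for antialiasing
    edge = np.clip((boundary - rr) + 0.5, 0.0, 1.0)
    mask = rr <= boundary
    rel = np.divide(rr, boundary, out=np.ones_like(rr), where=boundary > 0)
    pallor_dip = pallor * np.exp(-((rel / 0.55) ** 2))
    sprite = stain * edge * (1.0 - pallor_dip)
    return sprite.astype(np.float32), mask


def render_scan(
    params: SmearSimParams,
    rng: np.random.Generator,
    donor_id: str = "synthetic",
    storage_week: int = 0,
    scan_id: str = "scan_0",
) -> tuple[SmearScan, GroundTruth]:
    """Render a full synthetic smear scan with ground truth.

    The number of cells is Poisson with mean ``cells_per_tile`` per tile-area;
    positions are placed by rejection sampling that keeps cell centres at
    least 0.9 of the summed radii apart, except that a candidate closer than
    that is still accepted with probability ``overlap_rate`` (controlled
    clumping).  Cell types are i.i.d. Bernoulli(echinocyte_fraction).
    """
    h, w = params.image_size
    n_tiles = (h / params.tile_size) * (w / params.tile_size)
    n_cells = int(rng.poisson(params.cells_per_tile * n_tiles))
    background = params.background_level + (
        rng.normal(0.0, params.background_jitter) if params.background_jitter > 0 else 0.0
    )

    canvas = np.zeros((h, w), dtype=np.float32)
    mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    records = []
    margin = params.cell_radius_mean
    for _ in range(n_cells):
        cell_type = "echinocyte" if rng.random() < params.echinocyte_fraction else "discocyte"
        radius = float(
            np.clip(rng.normal(params.cell_radius_mean, params.cell_radius_sd), 4.0, None)
        )
        sprite, cell_mask = render_cell(cell_type, params, rng, radius=radius)
        half = sprite.shape[0] // 2
        for attempt in range(params.max_placement_attempts):
            cx = float(rng.uniform(margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            crowded = any(
                (cx - px) ** 2 + (cy - py) ** 2 < (0.9 * (radius + pr)) ** 2
                for px, py, pr in placed
            )
            if not crowded or rng.random() < params.overlap_rate:
                break
        else:
            raise SaturationError(
                f"could not place cell after {params.max_placement_attempts} attempts; "
                "reduce cells_per_tile or raise overlap_rate"
            )
        ix, iy = int(round(cx)), int(round(cy))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        sy0, sx0 = y0 - (iy - half), x0 - (ix - half)
        canvas[y0:y1, x0:x1] += sprite[sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)]
        mask[y0:y1, x0:x1] |= cell_mask[sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)]
        placed.append((cx, cy, radius))
        records.append({"cx": cx, "cy": cy, "radius": radius, "cell_type": cell_type})

    image = background - canvas
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    scan = SmearScan(
        pixels=image,
        donor_id=donor_id,
        storage_week=storage_week,
        scan_id=scan_id,
        bit_depth=14,
    )
    cells = pd.DataFrame(records, columns=["cx", "cy", "radius", "cell_type"])
    return scan, GroundTruth(cells=cells, mask=mask)


# ---------------------------------------------------------------------------
# Sorting simulator
# ---------------------------------------------------------------------------


def simulate_outlet_distribution(
    params: SortSimParams,
    rng: np.random.Generator,
    donor_id: str = "synthetic",
    storage_week: int = 0,
) -> OutletDistribution:
    """Draw latent rigidities ~ Normal(mu, sigma) and bin them into outlets.

    Discretization convention: ``outlet = clamp(ceil(latent), 1, 12)``, so a
    zero-dispersion population at mu = 3.2 lands entirely in outlet 4.
    """
    latent = rng.normal(params.mu, params.sigma, size=params.n_cells)
    outlets = np.clip(np.ceil(latent), 1, N_OUTLETS).astype(int)
    counts = np.bincount(outlets, minlength=N_OUTLETS + 1)[1:]
    return OutletDistribution(
        donor_id=donor_id,
        storage_week=storage_week,
        counts=tuple(int(c) for c in counts),
    )


def expected_outlet_probabilities(mu: float, sigma: float) -> np.ndarray:
    """Exact outlet probabilities of the clamped-ceiling latent model."""
    if sigma == 0:
        outlet = int(np.clip(math.ceil(mu), 1, N_OUTLETS))
        p = np.zeros(N_OUTLETS)
        p[outlet - 1] = 1.0
        return p
    upper = norm.cdf(np.arange(1, N_OUTLETS + 1), loc=mu, scale=sigma)
    upper[-1] = 1.0  # clamp folds both tails into outlets 1 and 12
    lower = np.concatenate([[0.0], upper[:-1]])
    lower[0] = 0.0
    return upper - lower


def analytic_rigidity_score(mu: float, sigma: float) -> float:
    """RS of the *expected* cumulative curve of the latent model.

    Inverts the piecewise-linear interpolation through (0, 0) and
    (k, P(outlet <= k)) at 50%; the large-sample limit of the simulated RS.
    """
    p = expected_outlet_probabilities(mu, sigma)
    F = np.concatenate([[0.0], np.cumsum(p)])
    k = int(np.searchsorted(F, 0.5, side="left"))
    return float(k - 1 + (0.5 - F[k - 1]) / (F[k] - F[k - 1]))


# ---------------------------------------------------------------------------
# Labelled corpus
# ---------------------------------------------------------------------------


@dataclass
class CorpusSample:
    scan: SmearScan
    truth: GroundTruth
    echinocyte_fraction: float
    rs: float
    bin_index: int


def make_labeled_corpus(
    rng: np.random.Generator,
    week_fractions: dict[int, float] | None = None,
    n_scans_per_class: int = 2,
    donor_ids: Sequence[str] = ("D1",),
    base_params: SmearSimParams | None = None,
) -> tuple[list[CorpusSample], pd.DataFrame]:
    """Generate scans + ground truth + manifest for all three learning tasks.

    Each storage week maps to an echinocyte fraction; every scan carries a
    storage label (the week), a continuous rigidity label ``rs_link(p_e)``
    and the corresponding deformability bin.  Scans cycle over ``donor_ids``.
    """
    if week_fractions is None:
        week_fractions = dict(DEFAULT_WEEK_ECHINOCYTE_FRACTIONS)
    base = base_params if base_params is not None else SmearSimParams()
    samples: list[CorpusSample] = []
    rows = []
    for week in sorted(week_fractions):
        p_e = week_fractions[week]
        rs = rs_link(p_e)
        for j in range(n_scans_per_class):
            donor = donor_ids[j % len(donor_ids)]
            scan_id = f"{donor}_w{week}_s{j}"
            params = replace(base, echinocyte_fraction=p_e)
            scan, truth = render_scan(
                params, rng, donor_id=donor, storage_week=week, scan_id=scan_id
            )
            bin_index = assign_bin(rs)
            samples.append(CorpusSample(scan, truth, p_e, rs, bin_index))
            rows.append(
                {
                    "scan_id": scan_id,
                    "donor_id": donor,
                    "storage_week": week,
                    "echinocyte_fraction": p_e,
                    "rs": rs,
                    "bin_index": bin_index,
                    "n_cells": len(truth.cells),
                }
            )
    manifest = pd.DataFrame(rows)
    return samples, manifest
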