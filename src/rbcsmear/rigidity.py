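"""Rigidity scores from microfluidic deformability-sorting outlet distributions.

A microfluidic ratchet device sorts red blood cells through progressively
narrowing tapered constrictions into twelve outlets: deformable cells squeeze
far down the constriction ladder (low outlet numbers), rigid cells are stopped
early (high outlet numbers).  The per-sample summary statistic is the
*rigidity score* (RS): the outlet number at which the linearly interpolated
cumulative sorted-cell distribution crosses 50 %.  Higher RS means a more
rigid cell population.

The RS is then discretized into four deformability categories
(RS < 2.50, 2.50-2.74, 2.75-2.99, > 2.99) that serve as classification
labels for the imaging pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_OUTLETS = 12

#: Funnel-constriction widths in micrometres, indexed by outlet 1..12.
#: The most deformable outlet (1) sits behind 1.5 um pores; the most rigid
#: outlet (12) behind 7.5 um pores.  Metadata only -- the RS computation uses
#: outlet indices, not physical pore widths.
DEFAULT_PORE_WIDTHS_UM: tuple[float, ...] = tuple(
    np.round(np.linspace(1.5, 7.5, N_OUTLETS), 3)
)

#: Upper bin edges of the four deformability categories (half-open intervals
#: [0, 2.50), [2.50, 2.75), [2.75, 3.00), [3.00, inf)).
BIN_EDGES: tuple[float, float, float] = (2.50, 2.75, 3.00)

BIN_LABELS: tuple[str, ...] = (
    "RS < 2.50",
    "RS 2.50-2.74",
    "RS 2.75-2.99",
    "RS > 2.99",
)


class InvalidDistributionError(ValueError):
    """Raised when an outlet distribution cannot support an RS computation."""


@dataclass(frozen=True)
class OutletDistribution:
    """Per-sample cell counts across the twelve deformability outlets.

    Parameters
    ----------
    donor_id:
        Opaque donor identifier.
    storage_week:
        Non-negative integer storage duration in weeks.
    counts:
        Twelve non-negative integers, ``counts[i]`` being the number of cells
        deposited in outlet ``i + 1``.
    pore_widths:
        Optional twelve constriction widths in micrometres (metadata).
    """

    donor_id: str
    storage_week: int
    counts: tuple[int, ...]
    pore_widths: tuple[float, ...] = field(default=DEFAULT_PORE_WIDTHS_UM)

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != N_OUTLETS:
            raise InvalidDistributionError(
                f"expected {N_OUTLETS} outlet counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise InvalidDistributionError("outlet counts must be non-negative")
        if len(self.pore_widths) != N_OUTLETS:
            raise InvalidDistributionError("expected 12 pore widths")
        if self.storage_week < 0:
            raise InvalidDistributionError("storage_week must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_cells(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class RigidityScore:
    """The RS statistic: 50 % crossover outlet of the cumulative distribution."""

    rs: float
    n_cells: int

    def __post_init__(self) -> None:
        if not (0.0 < self.rs <= N_OUTLETS):
            raise InvalidDistributionError(f"rs must lie in (0, 12], got {self.rs}")


def cumulative_curve(dist: OutletDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear cumulative sorted-cell distribution over [0, 12].

    Returns the node coordinates ``(x, F)`` of the monotone polyline anchored
    at ``(0, 0)`` and passing through ``(k, F(k))`` for outlets k = 1..12,
    where ``F(k)`` is the fraction of cells in outlets 1..k.  ``F(12) == 1``.

    Raises
    ------
    InvalidDistributionError
        If the distribution contains no cells.
    """
    total = dist.n_cells
    if total <= 0:
        raise InvalidDistributionError("cannot build a cumulative curve of 0 cells")
    x = np.arange(0, N_OUTLETS + 1, dtype=float)
    F = np.concatenate([[0.0], np.cumsum(dist.counts) / total])
    return x, F


def compute_rigidity_score(dist: OutletDistribution) -> RigidityScore:
    """Outlet number at the 50 % crossover of the cumulative curve.

    The crossover is the *smallest* x with F(x) = 0.5 under linear
    interpolation between the curve nodes; on a flat segment sitting exactly
    at 50 % the leftmost point is returned.
    """
    x, F = cumulative_curve(dist)
    # First node at or above 50%.  F[0] = 0, so k >= 1 and F[k-1] < 0.5;
    # interpolating on the segment [k-1, k] yields the leftmost crossover
    # (a flat segment sitting at exactly 0.5 starts at its left node).
    k = int(np.searchsorted(F, 0.5, side="left"))
    rs = float(x[k - 1]) + (0.5 - F[k - 1]) / (F[k] - F[k - 1])
    return RigidityScore(rs=rs, n_cells=dist.n_cells)


def assign_bin(rs: float | RigidityScore) -> int:
    """Map an RS value to its deformability category index 0..3.

    Half-open intervals [0, 2.50), [2.50, 2.75), [2.75, 3.00), [3.00, inf)
    partition the RS axis exhaustively.
    """
    value = rs.rs if isinstance(rs, RigidityScore) else float(rs)
    if not (0.0 < value <= N_OUTLETS):
        raise InvalidDistributionError(f"rs must lie in (0, 12], got {value}")
    return int(np.searchsorted(BIN_EDGES, value, side="right"))


def bin_membership_counts(
    assignments: Iterable[tuple[object, object, int]],
) -> tuple[int, int, int, int]:
    """Tally (donor, week, bin) assignments into per-bin sample counts."""
    counts = [0, 0, 0, 0]
    for _, _, bin_index in assignments:
        if not 0 <= int(bin_index) <= 3:
            raise ValueError(f"bin index out of range: {bin_index}")
        counts[int(bin_index)] += 1
    return tuple(counts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

OUTLET_COLUMNS = [f"outlet_{k}" for k in range(1, N_OUTLETS + 1)]


def read_outlet_csv(path: str | Path) -> list[OutletDistribution]:
    """Read a CSV with columns donor_id, storage_week, outlet_1 .. outlet_12."""
    df = pd.read_csv(path)
    missing = [c for c in ["donor_id", "storage_week", *OUTLET_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"outlet CSV missing columns: {missing}")
    return [
        OutletDistribution(
            donor_id=str(row["donor_id"]),
            storage_week=int(row["storage_week"]),
            counts=tuple(int(row[c]) for c in OUTLET_COLUMNS),
        )
        for _, row in df.iterrows()
    ]


def score_table(distributions: Sequence[OutletDistribution]) -> pd.DataFrame:
    """RS score table: donor_id, storage_week, n_cells, rs (4 dp), bin_index."""
    rows = []
    for dist in distributions:
        score = compute_rigidity_score(dist)
        rows.append(
            {
                "donor_id": dist.donor_id,
                "storage_week": dist.storage_week,
                "n_cells": score.n_cells,
                "rs": round(score.rs, 4),
                "bin_index": assign_bin(score),
            }
        )
    return pd.DataFrame(rows, columns=["donor_id", "storage_week", "n_cells", "rs", "bin_index"])


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        df.to_csv(path, index=False)
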