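"""Input-gradient saliency maps and overlays.

The saliency of a prediction is the absolute gradient of the target score
with respect to the input pixels, max-normalized to [0, 1].  For
classification targets the gradient of the pre-softmax logit is used (the
probability gradient saturates once the class is confidently predicted);
for regression the single output is differentiated directly.  The model runs
in evaluation mode (dropout off, batch-norm using running statistics), so
maps are deterministic for fixed weights and tile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from skimage.morphology import dilation, disk

from .nn import Model


@dataclass
class SaliencyMap:
    """Pixel attributions for one tile; values in [0, 1], same shape as input."""

    values: np.ndarray
    target: int | str
    provenance: tuple | None = None
    method: str = "input-gradient"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)


def compute_saliency(
    model: Model, tile: np.ndarray, target: int | str | None = None
) -> SaliencyMap:
    """Absolute input-gradient of the target score, max-normalized.

    ``target`` is a class index for classification heads (default: the
    predicted class) and is ignored for the regression head.
    """
    tile = np.asarray(tile, dtype=np.float32)
    x = tile.reshape(1, 1, *tile.shape[-2:])
    logits = model.forward(x, train=False)
    if model.task == "regression":
        target = "regression"
        dout = np.ones_like(logits)
    else:
        if target is None:
            target = int(logits.argmax())
        if not (0 <= int(target) < model.head_size):
            raise ValueError(
                f"target {target} out of range for a {model.head_size}-class head"
            )
        dout = np.zeros_like(logits)
        dout[0, int(target)] = 1.0
    grad = model.backward_to_input(dout)
    values = np.abs(grad[0, 0])
    peak = values.max()
    if peak > 0:
        values = values / peak
    return SaliencyMap(values=values, target=target)


def overlay(
    smap: SaliencyMap, tile: np.ndarray, alpha: float = 1.0, cmap: str = "hot"
) -> np.ndarray:
    """Warm-colormap alpha blend of a saliency map over the grayscale tile.

    Returns an (H, W, 3) uint8 image.  Pure visualization: a zero map
    reproduces the grayscale tile, a saturated map the colormap extreme.
    """
    tile = np.asarray(tile, dtype=np.float32)
    if smap.values.shape != tile.shape:
        raise ValueError("saliency map and tile shapes differ")
    span = np.ptp(tile)
    gray = (tile - tile.min()) / span if span > 0 else np.zeros_like(tile)
    gray_rgb = np.repeat(gray[..., None], 3, axis=-1)
    cmap_rgb = colormaps[cmap](smap.values)[..., :3]
    weight = (alpha * smap.values)[..., None]
    blended = (1.0 - weight) * gray_rgb + weight * cmap_rgb
    return (np.clip(blended, 0, 1) * 255).round().astype(np.uint8)


def cell_concentration_score(
    smap: SaliencyMap, cell_mask: np.ndarray, dilation_radius: int = 2
) -> float:
    """Fraction of total saliency mass inside the (dilated) cell mask."""
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != smap.values.shape:
        raise ValueError("cell mask and saliency map shapes differ")
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius))
    total = float(smap.values.sum())
    if total == 0:
        return 0.0
    return float(smap.values[mask].sum() / total)


def save_map(smap: SaliencyMap, path: str | Path) -> None:
    """16-bit PNG of the map plus a JSON metadata sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (smap.values * 65535).round().astype(np.uint16))
    meta = {
        "method": smap.method,
        "target": smap.target,
        "provenance": list(smap.provenance) if smap.provenance else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
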