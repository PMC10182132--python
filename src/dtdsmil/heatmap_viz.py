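"""Interpretability maps: patch probability map and MIL attention map.

The probability map places each patch's instance-classifier score at its
grid cell on an absolute [0, 1] scale.  The attention map places the MIL
attention weights min-max normalized per slide (relative saliency), since
attention weights are only meaningful relative to each other within one
slide.  Non-tissue cells are missing (NaN).  Overlays upsample each cell to
its patch footprint with nearest-neighbor interpolation so every rendered
block corresponds bit-exactly to one patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

from .dsmil_head import MILOutput
from .errors import DataError, DegenerateWarning
from .features import FeatureBag

KINDS = ("probability", "attention")


@dataclass
class HeatmapRaster:
    values: np.ndarray  # (n_rows, n_cols), NaN where no tissue
    kind: str
    normalization: str
    degenerate: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise DataError(f"unknown heatmap kind {self.kind!r}")
        valid = self.values[~np.isnan(self.values)]
        if valid.size and (valid.min() < 0.0 or valid.max() > 1.0):
            raise DataError("heatmap values must lie in [0, 1]")


def _place(bag: FeatureBag, cell_values: np.ndarray) -> np.ndarray:
    if len(cell_values) != bag.n:
        raise DataError("values and bag lengths differ")
    grid = np.full(bag.grid_shape, np.nan)
    rows, cols = bag.coords[:, 1], bag.coords[:, 0]
    if np.isfinite(grid[rows, cols]).any():
        raise DataError("coordinate collision while placing heatmap values")
    grid[rows, cols] = cell_values
    return grid


def probability_map(bag: FeatureBag, mil_output: MILOutput) -> HeatmapRaster:
    """Per-patch positive probability on an absolute scale."""
    return HeatmapRaster(_place(bag, mil_output.instance_scores),
                         kind="probability", normalization="absolute")


def attention_map(bag: FeatureBag, mil_output: MILOutput) -> HeatmapRaster:
    """Per-patch attention weights, min-max normalized over tissue cells.

    If all weights are equal (including the single-patch case) the map is
    flat 0.5 and flagged degenerate.
    """
    w = np.asarray(mil_output.attention, dtype=float)
    lo, hi = w.min(), w.max()
    degenerate = hi - lo <= 0.0
    if degenerate:
        warnings.warn("attention weights all equal; map is degenerate",
                      DegenerateWarning, stacklevel=2)
        norm = np.full_like(w, 0.5)
    else:
        norm = (w - lo) / (hi - lo)
    return HeatmapRaster(_place(bag, norm), kind="attention",
                         normalization="minmax", degenerate=degenerate)


def overlay(raster: HeatmapRaster, slide_image: np.ndarray,
            colormap: str = "jet", alpha: float = 0.5,
            patch_size: int | None = None) -> np.ndarray:
    """Alpha-blend a heatmap over the slide image it was computed from.

    Each grid cell is upsampled (nearest neighbor) to its ``patch_size``
    footprint; missing cells are fully transparent.  Returns a uint8 RGB
    image with the dimensions of ``slide_image``.
    """
    img = np.asarray(slide_image)
    H, W = img.shape[:2]
    n_rows, n_cols = raster.values.shape
    if patch_size is None:
        if H % n_rows or W % n_cols or H // n_rows != W // n_cols:
            raise DataError("cannot infer patch_size; pass it explicitly")
        patch_size = H // n_rows
    if n_rows * patch_size > H or n_cols * patch_size > W:
        raise DataError(
            f"heatmap {raster.values.shape} at patch_size {patch_size} "
            f"exceeds image {img.shape[:2]}")
    cmap = matplotlib.colormaps[colormap]
    up = np.kron(raster.values, np.ones((patch_size, patch_size)))
    valid = ~np.isnan(up)
    colored = cmap(np.nan_to_num(up))[..., :3] * 255.0
    out = img.astype(np.float64).copy()
    region = out[: up.shape[0], : up.shape[1]]
    blend = valid[..., None] * alpha
    region[:] = region * (1.0 - blend) + colored * blend
    return np.clip(out, 0, 255).astype(np.uint8)


def save_map_csv(raster: HeatmapRaster, path: str | Path) -> None:
    """Write the raw grid as CSV; missing cells use the sentinel 'NA'."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind={raster.kind} normalization={raster.normalization} "
                 "missing=NA\n")
        for row in raster.values:
            fh.write(",".join("NA" if np.isnan(v) else repr(float(v))
                              for v in row) + "\n")


def save_overlay_png(image: np.ndarray, path: str | Path) -> None:
    from PIL import Image
    Image.fromarray(image).save(path)
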