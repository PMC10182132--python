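"""Tissue segmentation and patch tiling.

Whole-slide rasters are segmented into tissue vs. background by thresholding
the HSV saturation channel (stained tissue is strongly saturated, glass
background is nearly gray), then tiled into a non-overlapping grid of
fixed-size square patches.  Coordinate conventions used everywhere in this
package:

* pixel origin is the top-left corner; ``pixel_y`` increases downward;
* grid cells are 0-based ``(row, col)`` with ``pixel_y = row * patch_size``
  and ``pixel_x = col * patch_size``;
* partial border cells (raster dimensions not divisible by ``patch_size``)
  are discarded, so the grid covers ``floor(H/p) x floor(W/p)`` cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DataError

MAGNIFICATIONS = ("5x", "10x", "20x", "40x")

#: nominal microns-per-pixel of each magnification for an Aperio-class
#: scanner whose 40x level is 0.25 um/px
NOMINAL_MPP = {"5x": 2.0, "10x": 1.0, "20x": 0.5, "40x": 0.25}


@dataclass
class SlideRaster:
    """An in-memory RGB slide level.

    ``magnification_label`` is advisory metadata; synthetic desk-scale rasters
    may use any microns-per-pixel.  Call :meth:`check_magnification` to verify
    consistency with the nominal scanner scale when working with real slides.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    magnification_label: str = "10x"
    slide_id: str = "slide"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError("pixels must be an H x W x 3 RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise DataError("raster must have at least one pixel")
        if self.microns_per_pixel <= 0:
            raise DataError("microns_per_pixel must be positive")
        if self.magnification_label not in MAGNIFICATIONS:
            raise ConfigurationError(
                f"unknown magnification label {self.magnification_label!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def check_magnification(self, rtol: float = 0.25) -> bool:
        nominal = NOMINAL_MPP[self.magnification_label]
        return abs(self.microns_per_pixel - nominal) <= rtol * nominal


@dataclass
class TissueMask:
    mask: np.ndarray
    threshold_used: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.threshold_used <= 1.0:
            raise DataError("threshold_used must lie in [0, 1]")


@dataclass
class PatchGrid:
    """Kept patches of a tissue-masked tiling.

    ``patches`` holds ``(row, col, pixel_y, pixel_x)`` per kept patch;
    ``tissue_fractions`` is aligned with ``patches``.
    """

    patch_size: int
    patches: list[tuple[int, int, int, int]]
    grid_shape: tuple[int, int]
    min_tissue_fraction: float
    level_microns_per_pixel: float
    tissue_fractions: list[float] = field(default_factory=list)
    slide_id: str = "slide"

    def __post_init__(self):
        n_rows, n_cols = self.grid_shape
        for row, col, py, px in self.patches:
            if not (0 <= row < n_rows and 0 <= col < n_cols):
                raise DataError(f"patch ({row},{col}) outside grid {self.grid_shape}")
            if py != row * self.patch_size or px != col * self.patch_size:
                raise DataError("pixel coords inconsistent with (row, col)")

    def __len__(self) -> int:
        return len(self.patches)


def compute_tissue_mask(raster: SlideRaster, threshold_mode: str = "otsu",
                        fixed_threshold: float | None = None) -> TissueMask:
    """Segment tissue by thresholding the HSV saturation channel.

    ``threshold_mode`` is ``"otsu"`` (data-driven threshold on the saturation
    histogram) or ``"fixed"`` (caller-supplied ``fixed_threshold``).  A pixel
    is tissue iff its saturation strictly exceeds the threshold.
    """
    sat = rgb2hsv(raster.pixels)[..., 1]
    if threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ConfigurationError("fixed mode requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_mode == "otsu":
        if np.ptp(sat) == 0.0:
            # constant saturation: nothing to separate
            thr = float(sat.flat[0])
        else:
            thr = float(threshold_otsu(sat))
    else:
        raise ConfigurationError(f"unknown threshold_mode {threshold_mode!r}")
    return TissueMask(mask=sat > thr, threshold_used=min(max(thr, 0.0), 1.0))


def tile(mask: TissueMask, patch_size: int, min_tissue_fraction: float = 0.25,
         level_microns_per_pixel: float = 1.0, slide_id: str = "slide") -> PatchGrid:
    """Tile a tissue mask into a non-overlapping grid of square patches.

    Cells whose tissue fraction is >= ``min_tissue_fraction`` are kept
    (a zero threshold keeps every cell).  Partial border cells are discarded.
    """
    if patch_size < 1:
        raise ConfigurationError("patch_size must be >= 1")
    H, W = mask.mask.shape
    n_rows, n_cols = H // patch_size, W // patch_size
    patches: list[tuple[int, int, int, int]] = []
    fractions: list[float] = []
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"patch_size {patch_size} exceeds raster dimensions ({H}x{W}); "
            "empty grid", stacklevel=2)
        return PatchGrid(patch_size, [], (n_rows, n_cols), min_tissue_fraction,
                         level_microns_per_pixel, [], slide_id)
    cropped = mask.mask[: n_rows * patch_size, : n_cols * patch_size]
    frac = cropped.reshape(n_rows, patch_size, n_cols, patch_size).mean(axis=(1, 3))
    for row in range(n_rows):
        for col in range(n_cols):
            if frac[row, col] >= min_tissue_fraction:
                patches.append((row, col, row * patch_size, col * patch_size))
                fractions.append(float(frac[row, col]))
    return PatchGrid(patch_size, patches, (n_rows, n_cols), min_tissue_fraction,
                     level_microns_per_pixel, fractions, slide_id)


def crop_patch(raster: SlideRaster, grid: PatchGrid, index: int) -> np.ndarray:
    """Return the exact pixel block of patch ``index`` of the grid."""
    if not 0 <= index < len(grid.patches):
        raise IndexError(f"patch index {index} out of range [0, {len(grid.patches)})")
    _, _, py, px = grid.patches[index]
    p = grid.patch_size
    return raster.pixels[py: py + p, px: px + p]


def iter_patches(raster: SlideRaster, grid: PatchGrid):
    for i in range(len(grid.patches)):
        yield crop_patch(raster, grid, i)


# -- I/O ------------------------------------------------------------------

def save_grid_csv(grid: PatchGrid, path: str | Path) -> None:
    rows = [
        {"slide_id": grid.slide_id, "row": r, "col": c,
         "pixel_y": py, "pixel_x": px, "tissue_fraction": f}
        for (r, c, py, px), f in zip(grid.patches, grid.tissue_fractions)
    ]
    pd.DataFrame(rows, columns=["slide_id", "row", "col", "pixel_y", "pixel_x",
                                "tissue_fraction"]).to_csv(path, index=False)


def load_raster(path: str | Path, microns_per_pixel: float,
                magnification_label: str = "10x",
                target_mpp: float | None = None) -> SlideRaster:
    """Read a raster image into a :class:`SlideRaster`.

    PNG/TIFF files are read directly with Pillow.  Pyramidal formats (.svs)
    require the optional ``openslide`` reader; when present, the pyramid
    level nearest ``target_mpp`` is read.
    """
    path = Path(path)
    if path.suffix.lower() == ".svs":
        try:
            import openslide  # optional dependency
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "reading pyramidal .svs slides requires openslide-python"
            ) from exc
        slide = openslide.OpenSlide(str(path))  # pragma: no cover
        base_mpp = float(slide.properties.get("openslide.mpp-x", microns_per_pixel))
        want = target_mpp or microns_per_pixel
        level = min(range(slide.level_count),
                    key=lambda l: abs(base_mpp * slide.level_downsamples[l] - want))
        img = slide.read_region((0, 0), level, slide.level_dimensions[level])
        arr = np.asarray(img.convert("RGB"))
        mpp = base_mpp * slide.level_downsamples[level]
        return SlideRaster(arr, mpp, magnification_label, path.stem)
    arr = np.asarray(Image.open(path).convert("RGB"))
    return SlideRaster(arr, microns_per_pixel, magnification_label, path.stem)
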