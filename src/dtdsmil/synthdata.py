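"""Synthetic data generators and the dataset splitter.

Two generators make every pipeline stage testable without any download:

* :func:`gen_feature_bags` emits feature-space bags obeying the standard
  MIL assumption — a bag is positive iff it contains at least one positive
  instance.  Negative instances are isotropic Gaussian noise; positive
  instances are shifted along one fixed unit direction.
* :func:`gen_slide_image` renders a pseudo-slide: saturated tissue disks
  ("lymph nodes") on a gray background, with optional lesion disks of a
  distinct texture inside positive nodes.  Lesion diameters respect the CAP
  metastasis size classes at the stated microns-per-pixel: isolated tumor
  cells < 0.2 mm, micro-metastasis 0.2-2.0 mm, macro-metastasis > 2.0 mm.

:func:`split_dataset` implements the 70:10:20 train/validation/test split
with floor/floor/remainder rounding and optional stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .features import FeatureBag

LESION_CLASSES = ("none", "itc", "micro", "macro")
#: CAP diameter bounds in microns per lesion class (lo inclusive, hi exclusive)
LESION_BOUNDS_UM = {"itc": (40.0, 200.0), "micro": (200.0, 2000.0),
                    "macro": (2000.0, np.inf)}


@dataclass
class SyntheticBagSpec:
    n_bags: int = 300
    instances_per_bag: int = 64
    d: int = 32
    pos_bag_fraction: float = 0.5
    pos_instance_fraction: float = 0.1
    mean_shift: float = 2.0
    noise_sd: float = 1.0
    grid_shape: tuple[int, int] = (8, 8)
    seed: int = 7

    def __post_init__(self):
        if not 0.0 < self.pos_instance_fraction <= 1.0:
            raise ConfigurationError("pos_instance_fraction must be in (0, 1]")
        if self.noise_sd <= 0 or self.mean_shift < 0:
            raise ConfigurationError("noise_sd > 0 and mean_shift >= 0 required")
        if self.instances_per_bag > self.grid_shape[0] * self.grid_shape[1]:
            raise ConfigurationError("more instances than grid cells")


@dataclass
class SyntheticSlideSpec:
    image_size: tuple[int, int] = (768, 768)
    n_nodes: int = 3
    node_radius_range: tuple[int, int] = (70, 95)
    lesion_class: str = "macro"
    pos_node_fraction: float = 1.0
    microns_per_pixel: float = 20.0
    background_rgb: tuple[int, int, int] = (205, 205, 205)
    tissue_rgb: tuple[int, int, int] = (228, 140, 160)
    lesion_rgb: tuple[int, int, int] = (120, 60, 160)
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.lesion_class not in LESION_CLASSES:
            raise ConfigurationError(f"unknown lesion class {self.lesion_class!r}")
        if self.microns_per_pixel <= 0:
            raise ConfigurationError("microns_per_pixel must be positive")


def gen_feature_bags(spec: SyntheticBagSpec):
    """Generate MIL feature bags with ground-truth instance labels.

    Returns ``(bags, bag_labels, instance_labels)``.  Positive bags carry
    ``ceil(pos_instance_fraction * N)`` positive instances (at least one);
    instances occupy distinct grid cells.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(size=spec.d)
    u /= np.linalg.norm(u)
    n_pos_bags = int(round(spec.pos_bag_fraction * spec.n_bags))
    bag_labels = np.zeros(spec.n_bags, dtype=int)
    bag_labels[rng.choice(spec.n_bags, size=n_pos_bags, replace=False)] = 1

    n_inst = spec.instances_per_bag
    n_pos_inst = int(np.ceil(spec.pos_instance_fraction * n_inst))
    if n_pos_inst == 0:
        warnings.warn("pos_instance_fraction rounded to 0 instances; forcing 1",
                      stacklevel=2)
        n_pos_inst = 1

    n_rows, n_cols = spec.grid_shape
    cells = np.stack(np.meshgrid(np.arange(n_cols), np.arange(n_rows)),
                     axis=-1).reshape(-1, 2)  # (x, y) pairs
    bags, instance_labels = [], []
    for b in range(spec.n_bags):
        coords = cells[rng.choice(len(cells), size=n_inst, replace=False)]
        inst = np.zeros(n_inst, dtype=int)
        if bag_labels[b] == 1:
            inst[rng.choice(n_inst, size=n_pos_inst, replace=False)] = 1
        tokens = rng.normal(0.0, spec.noise_sd, size=(n_inst, spec.d))
        tokens[inst == 1] += spec.mean_shift * u
        bags.append(FeatureBag(tokens=tokens, coords=coords,
                               grid_shape=spec.grid_shape,
                               slide_id=f"bag{b:04d}",
                               label=int(bag_labels[b])))
        instance_labels.append(inst)
    return bags, bag_labels, instance_labels


def lesion_diameter_px(lesion_class: str, microns_per_pixel: float,
                       max_diameter_px: float,
                       rng: np.random.Generator) -> float:
    """Sample a lesion diameter in pixels respecting the class bounds."""
    lo_um, hi_um = LESION_BOUNDS_UM[lesion_class]
    lo = lo_um / microns_per_pixel
    hi = min(hi_um / microns_per_pixel, max_diameter_px)
    if hi <= lo:
        raise ConfigurationError(
            f"{lesion_class} lesion cannot fit: needs > {lo:.1f} px but only "
            f"{max_diameter_px:.1f} px available at "
            f"{microns_per_pixel} um/px")
    return float(rng.uniform(lo + 1e-9, hi))


def gen_slide_image(spec: SyntheticSlideSpec):
    """Render a pseudo-slide with ground truth.

    Returns ``(raster_pixels, node_boxes, node_labels, lesion_masks)`` where
    ``node_boxes`` are half-open ``(x_min, y_min, x_max, y_max)`` pixel
    boxes, ``node_labels`` binary per node, and ``lesion_masks`` boolean
    full-size masks (empty where the node is negative).  Importing
    :class:`~dtdsmil.tiling.SlideRaster` is left to the caller to avoid an
    import cycle; wrap the pixels yourself or use
    :func:`gen_slide_raster`.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    r_lo, r_hi = spec.node_radius_range
    centers, radii = [], []
    for _node in range(spec.n_nodes):
        placed = False
        for _try in range(2000):
            r = int(rng.integers(r_lo, r_hi + 1))
            cy = int(rng.integers(r + 2, H - r - 2))
            cx = int(rng.integers(r + 2, W - r - 2))
            if all(np.hypot(cy - oy, cx - ox) > r + orr + 8
                   for (oy, ox), orr in zip(centers, radii)):
                centers.append((cy, cx))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise DataError(
                f"could not place {spec.n_nodes} disjoint nodes in "
                f"{spec.image_size} after bounded retries")

    if spec.lesion_class == "none":
        positive = np.zeros(spec.n_nodes, dtype=bool)
    else:
        n_pos = int(round(spec.pos_node_fraction * spec.n_nodes))
        positive = np.zeros(spec.n_nodes, dtype=bool)
        positive[rng.choice(spec.n_nodes, size=n_pos, replace=False)] = True

    yy, xx = np.mgrid[0:H, 0:W]
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    node_boxes, node_labels, lesion_masks = [], [], []
    for node_i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[disk] = spec.tissue_rgb
        lesion_mask = np.zeros((H, W), dtype=bool)
        label = 0
        if positive[node_i]:
            diam = lesion_diameter_px(spec.lesion_class,
                                      spec.microns_per_pixel,
                                      max_diameter_px=1.6 * r, rng=rng)
            lr = diam / 2.0
            # keep the lesion inside the node
            max_off = max(r - lr - 2.0, 0.0)
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max_off)
            ly, lx = cy + off * np.sin(ang), cx + off * np.cos(ang)
            lesion_mask = ((yy - ly) ** 2 + (xx - lx) ** 2 <= lr ** 2) & disk
            img[lesion_mask] = spec.lesion_rgb
            label = 1
        node_boxes.append((cx - r, cy - r, cx + r + 1, cy + r + 1))
        node_labels.append(label)
        lesion_masks.append(lesion_mask)
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return pixels, node_boxes, np.array(node_labels), lesion_masks


def gen_slide_raster(spec: SyntheticSlideSpec, slide_id: str = "synthetic"):
    """Like :func:`gen_slide_image` but wrapping pixels in a SlideRaster."""
    from .tiling import SlideRaster
    pixels, boxes, labels, masks = gen_slide_image(spec)
    raster = SlideRaster(pixels, spec.microns_per_pixel, "5x", slide_id)
    return raster, boxes, labels, masks


def upscale_raster(raster, factor: int):
    """Nearest-neighbor upscale emulating a higher magnification rescan."""
    from .tiling import SlideRaster
    pixels = np.repeat(np.repeat(raster.pixels, factor, axis=0), factor, axis=1)
    return SlideRaster(pixels, raster.microns_per_pixel / factor,
                       raster.magnification_label, raster.slide_id)


def split_dataset(n_items: int, labels=None, ratios=(0.7, 0.1, 0.2),
                  stratified: bool = False, seed: int = 0):
    """Random train/val/test split with floor/floor/remainder sizes.

    Split sizes are ``floor(r1*n)``, ``floor(r2*n)`` and the remainder.  In
    stratified mode classes are allocated to splits proportionally, filling
    fractional leftovers by largest remainder, so the class distribution is
    preserved and the split sizes are unchanged.
    """
    ratios = np.asarray(ratios, dtype=float)
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ConfigurationError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    sizes = [int(np.floor(ratios[0] * n_items)),
             int(np.floor(ratios[1] * n_items))]
    sizes.append(n_items - sizes[0] - sizes[1])

    if not stratified or labels is None:
        perm = rng.permutation(n_items)
        a, b = sizes[0], sizes[0] + sizes[1]
        return perm[:a], perm[a:b], perm[b:]

    labels = np.asarray(labels)
    classes = np.unique(labels)
    # floor allocation per (class, split) cell, then largest-remainder fill
    quota = {}
    alloc = {}
    for c in classes:
        n_c = int((labels == c).sum())
        q = ratios * n_c
        f = np.floor(q).astype(int)
        quota[c] = q - f
        alloc[c] = f
    deficit = [sizes[s] - sum(alloc[c][s] for c in classes) for s in range(3)]
    leftover = {c: int((labels == c).sum()) - int(alloc[c].sum())
                for c in classes}
    cells = sorted(((float(quota[c][s]), str(c), s)
                    for c in classes for s in range(3)), reverse=True)
    for _rem, c_str, s in cells:
        c = classes[[str(x) for x in classes].index(c_str)]
        if leftover[c] > 0 and deficit[s] > 0:
            alloc[c][s] += 1
            leftover[c] -= 1
            deficit[s] -= 1
    # any stragglers (remainder ordering exhausted a split): place greedily
    for c in classes:
        while leftover[c] > 0:
            s = int(np.argmax(deficit))
            alloc[c][s] += 1
            leftover[c] -= 1
            deficit[s] -= 1

    splits = [[], [], []]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        a = alloc[c][0]
        b = a + alloc[c][1]
        splits[0].extend(idx[:a])
        splits[1].extend(idx[a:b])
        splits[2].extend(idx[b:])
        for s in range(3):
            if alloc[c][s] == 0:
                warnings.warn(
                    f"class {c!r} received no items in split {s}",
                    stacklevel=2)
    return (np.array(sorted(splits[0])), np.array(sorted(splits[1])),
            np.array(sorted(splits[2])))


def default_benchmark(seed: int = 7, mean_shift: float = 2.0):
    """The default synthetic bag benchmark: 200 train / 100 test bags.

    Generates 300 bags (64 instances on an 8x8 grid, d=32, half the bags
    positive with 10% positive instances, unit noise) and slices the first
    200 for training and the last 100 for testing.
    """
    spec = SyntheticBagSpec(n_bags=300, mean_shift=mean_shift, seed=seed)
    bags, bag_labels, inst_labels = gen_feature_bags(spec)
    return ((bags[:200], bag_labels[:200], inst_labels[:200]),
            (bags[200:], bag_labels[200:], inst_labels[200:]))
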