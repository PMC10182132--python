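"""Patch feature extraction and per-slide feature bags.

A :class:`FeatureBag` is the central exchange object between all model
stages: one fixed-dimension token per tissue patch, with its grid coordinate
``(x, y) = (col, row)``.  Bags are saved as a binary token array plus a CSV
coordinate sidecar and a JSON metadata file, so they are streamable and
language-neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._backbones import ResNet50Topology, TinyTestCNN
from .errors import ConfigurationError, DataError, NoTissueError, ParseError
from .tiling import PatchGrid, SlideRaster, crop_patch

BACKBONE_NAMES = ("resnet50_imagenet_topology", "tiny_test_cnn", "external")


@dataclass
class FeatureBag:
    """Per-slide set of patch feature tokens with grid coordinates.

    ``tokens`` is N x d; ``coords`` is N x 2 holding ``(x, y) = (col, row)``
    grid indices (0-based, row increasing downward).
    """

    tokens: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int]
    slide_id: str = "slide"
    label: int | None = None

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 1:
            raise NoTissueError("a feature bag needs at least one token")
        if self.coords.shape != (self.tokens.shape[0], 2):
            raise DataError("coords must be N x 2, aligned with tokens")
        n_rows, n_cols = self.grid_shape
        x, y = self.coords[:, 0], self.coords[:, 1]
        if (x < 0).any() or (x >= n_cols).any() or (y < 0).any() or (y >= n_rows).any():
            raise DataError("coords outside grid_shape")
        if len({(int(a), int(b)) for a, b in self.coords}) != len(self.coords):
            raise DataError("duplicate patch coordinates in bag")
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise DataError("label must be binary")

    @property
    def n(self) -> int:
        return self.tokens.shape[0]

    @property
    def d(self) -> int:
        return self.tokens.shape[1]

    def with_tokens(self, tokens: np.ndarray) -> "FeatureBag":
        return replace(self, tokens=np.asarray(tokens, dtype=np.float64))


@dataclass
class BackboneSpec:
    name: str
    output_dim: int
    weights_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in BACKBONE_NAMES:
            raise ConfigurationError(f"unknown backbone {self.name!r}")
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")


class _ExternalBackbone:
    def __init__(self, fn, output_dim: int):
        self.fn = fn
        self.output_dim = int(output_dim)

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        out = np.asarray(self.fn(patches), dtype=np.float64)
        if out.ndim != 2 or out.shape[1] != self.output_dim:
            raise ConfigurationError(
                f"external backbone returned dim {out.shape[-1]}, "
                f"declared output_dim is {self.output_dim}")
        return out


def _load_weights(path: str) -> dict[str, np.ndarray]:
    try:
        with np.load(path) as npz:
            return {k: npz[k] for k in npz.files}
    except OSError as exc:
        raise OSError(f"cannot read backbone weights at {path}: {exc}") from exc


def build_backbone(spec: BackboneSpec, external_fn=None):
    """Instantiate a feature extractor from its spec.

    The returned handle maps a batch of HxWx3 patches to a batch of
    ``output_dim`` feature vectors.  ``weights_path`` (an ``.npz``) lets
    externally pretrained weights — e.g. from SimCLR pretraining — drop in
    without changing the contract.
    """
    weights = _load_weights(spec.weights_path) if spec.weights_path else None
    if spec.name == "tiny_test_cnn":
        return TinyTestCNN(output_dim=spec.output_dim, seed=spec.seed,
                           weights=weights)
    if spec.name == "resnet50_imagenet_topology":
        if spec.output_dim != ResNet50Topology.output_dim:
            raise ConfigurationError(
                "resnet50 topology emits 2048-d features; "
                f"spec declares {spec.output_dim}")
        return ResNet50Topology(seed=spec.seed, weights=weights)
    if external_fn is None:
        raise ConfigurationError("external backbone requires external_fn")
    return _ExternalBackbone(external_fn, spec.output_dim)


def extract_bag(raster: SlideRaster, grid: PatchGrid, backbone,
                batch_size: int = 32) -> FeatureBag:
    """Run the backbone over every kept patch, in grid order, batched.

    Token row order equals ``grid.patches`` order regardless of batch size.
    """
    if len(grid.patches) == 0:
        raise NoTissueError(f"grid for slide {grid.slide_id!r} has no tissue patches")
    chunks = []
    for start in range(0, len(grid.patches), batch_size):
        batch = np.stack([
            crop_patch(raster, grid, i)
            for i in range(start, min(start + batch_size, len(grid.patches)))
        ])
        chunks.append(np.asarray(backbone(batch), dtype=np.float64))
    tokens = np.concatenate(chunks, axis=0)
    coords = np.array([(c, r) for r, c, _, _ in grid.patches], dtype=np.int64)
    return FeatureBag(tokens=tokens, coords=coords, grid_shape=grid.grid_shape,
                      slide_id=grid.slide_id)


# -- bag persistence ------------------------------------------------------

def save_bag(bag: FeatureBag, outdir: str | Path) -> dict[str, Path]:
    """Write ``<slide_id>.tokens.npy`` + ``.bag.csv`` + ``.bag.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tokens": outdir / f"{bag.slide_id}.tokens.npy",
        "coords": outdir / f"{bag.slide_id}.bag.csv",
        "meta": outdir / f"{bag.slide_id}.bag.json",
    }
    np.save(paths["tokens"], bag.tokens)
    pd.DataFrame({
        "idx": np.arange(bag.n),
        "row": bag.coords[:, 1],
        "col": bag.coords[:, 0],
    }).to_csv(paths["coords"], index=False)
    paths["meta"].write_text(json.dumps({
        "slide_id": bag.slide_id,
        "d": bag.d,
        "grid_shape": list(bag.grid_shape),
        "label": bag.label,
    }))
    return paths


def load_bag(outdir: str | Path, slide_id: str) -> FeatureBag:
    """Lossless inverse of :func:`save_bag` (tokens bit-exact)."""
    outdir = Path(outdir)
    meta_path = outdir / f"{slide_id}.bag.json"
    csv_path = outdir / f"{slide_id}.bag.csv"
    npy_path = outdir / f"{slide_id}.tokens.npy"
    for p, fieldname in ((meta_path, "metadata"), (csv_path, "coords"),
                         (npy_path, "tokens")):
        if not p.exists():
            raise ParseError(f"missing {fieldname} file for bag {slide_id!r}: {p}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"corrupt metadata for bag {slide_id!r}: {exc}") from exc
    table = pd.read_csv(csv_path)
    for col in ("row", "col"):
        if col not in table.columns:
            raise ParseError(f"coords file for bag {slide_id!r} missing column {col!r}")
    tokens = np.load(npy_path)
    if tokens.shape[0] == 0:
        raise NoTissueError(f"bag {slide_id!r} contains no tokens")
    if tokens.shape[0] != len(table):
        raise ParseError(
            f"bag {slide_id!r}: tokens rows ({tokens.shape[0]}) != "
            f"coords rows ({len(table)})")
    coords = np.stack([table["col"].to_numpy(), table["row"].to_numpy()], axis=1)
    return FeatureBag(tokens=tokens, coords=coords,
                      grid_shape=tuple(meta["grid_shape"]),
                      slide_id=meta["slide_id"], label=meta["label"])
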