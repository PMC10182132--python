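"""Two-axis sinusoidal absolute position embedding for patch tokens.

A token at grid position (x, y) receives a d_model-length embedding built
from two d_model/2 per-axis halves, concatenated as [x-half || y-half].
Within a half, element 2i is sin(pos / base^(2i/D)) and element 2i+1 is
cos(pos / base^(2i/D)).  The normalizer D is the per-axis length by default
(the standard 2D sinusoidal construction); normalizing by the full model
width is selectable via ``normalizer_dim="full_model"``.  Embeddings are
added dimension-wise to the feature tokens; (x, y) are grid column/row
indices, not pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .features import FeatureBag

NORMALIZERS = ("per_axis", "full_model")


@dataclass
class PosEmbedConfig:
    d_model: int
    base: float = 10000.0
    normalizer_dim: str = "per_axis"

    def __post_init__(self):
        if self.d_model % 2 != 0 or (self.d_model // 2) % 2 != 0:
            raise ConfigurationError("d_model and d_model/2 must both be even")
        if self.normalizer_dim not in NORMALIZERS:
            raise ConfigurationError(
                f"normalizer_dim must be one of {NORMALIZERS}")

    @property
    def d_axis(self) -> int:
        return self.d_model // 2

    @property
    def _normalizer(self) -> int:
        return self.d_axis if self.normalizer_dim == "per_axis" else self.d_model


def axis_embedding(pos: int, cfg: PosEmbedConfig) -> np.ndarray:
    """Sinusoidal embedding of a single non-negative axis position."""
    if pos < 0:
        raise ValueError("position must be non-negative")
    two_i = np.arange(0, cfg.d_axis, 2, dtype=np.float64)
    angles = pos / cfg.base ** (two_i / cfg._normalizer)
    out = np.empty(cfg.d_axis)
    out[0::2] = np.sin(angles)
    out[1::2] = np.cos(angles)
    return out


def embed_2d(x: int, y: int, cfg: PosEmbedConfig) -> np.ndarray:
    """Concatenated [x-axis || y-axis] embedding, length d_model."""
    return np.concatenate([axis_embedding(x, cfg), axis_embedding(y, cfg)])


def embed_coords(coords: np.ndarray, cfg: PosEmbedConfig) -> np.ndarray:
    """Vectorized embed_2d over an N x 2 (x, y) coordinate array."""
    coords = np.asarray(coords)
    if (coords < 0).any():
        raise ValueError("positions must be non-negative")
    two_i = np.arange(0, cfg.d_axis, 2, dtype=np.float64)
    inv_freq = cfg.base ** (-two_i / cfg._normalizer)
    out = np.empty((coords.shape[0], cfg.d_model))
    for axis in (0, 1):
        angles = coords[:, axis, None] * inv_freq[None, :]
        half = np.empty((coords.shape[0], cfg.d_axis))
        half[:, 0::2] = np.sin(angles)
        half[:, 1::2] = np.cos(angles)
        out[:, axis * cfg.d_axis: (axis + 1) * cfg.d_axis] = half
    return out


def add_positions(bag: FeatureBag, cfg: PosEmbedConfig) -> FeatureBag:
    """Dimension-wise addition of position embeddings to the bag tokens."""
    if bag.d != cfg.d_model:
        raise ConfigurationError(
            f"bag token dim {bag.d} != posembed d_model {cfg.d_model}")
    return bag.with_tokens(bag.tokens + embed_coords(bag.coords, cfg))
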