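"""Encoder-only deformable transformer over the 2D patch-token grid.

Tokens are scattered to their (row, col) grid cells (non-tissue cells stay
zero and are marked invalid), and each encoder block applies single-level
deformable self-attention in the Deformable-DETR form: per query and head,
a learned linear map predicts ``n_points`` continuous sampling offsets and
logits; attention weights are a softmax over the points; sampled values are
read off the value map by bilinear interpolation (zeros outside the grid).
Blocks are post-norm residual: attention + LayerNorm, then a GeLU
feed-forward network + LayerNorm.

Offsets and logits are zero-initialized, so an untrained layer attends
uniformly to its own reference location — training starts as local
sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ConfigurationError, DataError
from .features import FeatureBag


@dataclass
class EncoderConfig:
    d_enc: int = 256
    n_layers: int = 2
    n_heads: int = 8
    n_points: int = 4
    d_ffn: int = 1024
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.d_enc % self.n_heads != 0:
            raise ConfigurationError("d_enc must be divisible by n_heads")
        if self.n_points < 1 or self.n_layers < 0:
            raise ConfigurationError("n_points >= 1 and n_layers >= 0 required")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")


@dataclass
class GridTensorState:
    """Dense grid view of a projected bag.

    ``value_map`` is (n_rows, n_cols, d_enc) with zeros outside
    ``validity_mask``; ``reference_points`` are normalized (x, y) cell
    centers in bag token order; ``rows``/``cols`` record that order.
    """

    value_map: np.ndarray
    validity_mask: np.ndarray
    reference_points: np.ndarray
    rows: np.ndarray
    cols: np.ndarray


def make_reference_points(grid_shape: tuple[int, int],
                          validity_mask: np.ndarray | None = None,
                          coords: np.ndarray | None = None) -> np.ndarray:
    """Normalized (x, y) cell centers: cell (r, c) -> ((c+.5)/C, (r+.5)/R).

    Order follows ``coords`` (an N x 2 (col, row) array) when given,
    otherwise row-major over the valid cells of ``validity_mask``.
    """
    n_rows, n_cols = grid_shape
    if coords is not None:
        cols = np.asarray(coords)[:, 0]
        rows = np.asarray(coords)[:, 1]
    else:
        if validity_mask is None:
            validity_mask = np.ones(grid_shape, dtype=bool)
        rows, cols = np.nonzero(validity_mask)
    if len(rows) == 0:
        raise DataError("at least one valid cell is required")
    return np.stack([(cols + 0.5) / n_cols, (rows + 0.5) / n_rows], axis=1)


def bilinear_sample(value_map: np.ndarray, point) -> np.ndarray:
    """Sample one normalized (x, y) location; zeros outside the grid."""
    vm = ad.constant(np.asarray(value_map, dtype=np.float64))
    pt = ad.constant(np.asarray(point, dtype=np.float64).reshape(1, 2))
    return ad.bilinear_sample_grid(vm, pt).data[0]


class Linear:
    """Dense layer holding parameter tensors; optionally bias-free."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None, bias: bool = True,
                 zero: bool = False):
        if zero:
            w = np.zeros((d_in, d_out))
        else:
            s = scale if scale is not None else math.sqrt(1.0 / d_in)
            w = rng.normal(0.0, s, size=(d_in, d_out))
        self.W = ad.parameter(w)
        self.b = ad.parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def params(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def set_identity(self) -> None:
        d_in, d_out = self.W.data.shape
        if d_in != d_out:
            raise ConfigurationError("identity projection needs square weights")
        self.W.data = np.eye(d_in)
        if self.b is not None:
            self.b.data = np.zeros(d_out)


class DeformableAttentionLayer:
    """One encoder block: deformable self-attention + FFN, post-norm."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d, H, K = cfg.d_enc, cfg.n_heads, cfg.n_points
        self.cfg = cfg
        self.offset_net = Linear(d, H * K * 2, rng, zero=True)
        self.logit_net = Linear(d, H * K, rng, zero=True)
        # bias-free so empty (non-tissue) cells stay exactly zero in the map
        self.value_proj = Linear(d, d, rng, bias=False)
        self.out_proj = Linear(d, d, rng)
        self.ffn1 = Linear(d, cfg.d_ffn, rng)
        self.ffn2 = Linear(cfg.d_ffn, d, rng)
        self.ln1_g = ad.parameter(np.ones(d))
        self.ln1_b = ad.parameter(np.zeros(d))
        self.ln2_g = ad.parameter(np.ones(d))
        self.ln2_b = ad.parameter(np.zeros(d))

    def params(self) -> list[Tensor]:
        ps = []
        for lin in (self.offset_net, self.logit_net, self.value_proj,
                    self.out_proj, self.ffn1, self.ffn2):
            ps.extend(lin.params())
        ps += [self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]
        return ps

    def attention(self, tokens: Tensor, rows: np.ndarray, cols: np.ndarray,
                  grid_shape: tuple[int, int], ref: Tensor) -> Tensor:
        cfg = self.cfg
        d, H, K = cfg.d_enc, cfg.n_heads, cfg.n_points
        dh = d // H
        N = tokens.data.shape[0]
        if tokens.data.shape[1] != d:
            raise ConfigurationError(
                f"query dim {tokens.data.shape[1]} != d_enc {d}")
        offsets = self.offset_net(tokens).reshape(N, H, K, 2)
        logits = self.logit_net(tokens).reshape(N, H, K)
        attn = ad.softmax(logits, axis=-1)
        vmap = ad.scatter_grid(self.value_proj(tokens), rows, cols, grid_shape)
        head_outs = []
        for h in range(H):
            vmap_h = vmap[:, :, h * dh:(h + 1) * dh]
            pts = (ref.reshape(N, 1, 2) + offsets[:, h]).reshape(N * K, 2)
            samp = ad.bilinear_sample_grid(vmap_h, pts).reshape(N, K, dh)
            w = attn[:, h].reshape(N, K, 1)
            head_outs.append((samp * w).sum(axis=1))
        return self.out_proj(ad.concat(head_outs, axis=-1))

    def forward(self, tokens: Tensor, rows, cols, grid_shape, ref: Tensor,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.cfg
        a = self.attention(tokens, rows, cols, grid_shape, ref)
        x = ad.layer_norm(tokens + ad.dropout(a, cfg.dropout, rng, training),
                          self.ln1_g, self.ln1_b)
        f = self.ffn2(ad.gelu(self.ffn1(x)))
        return ad.layer_norm(x + ad.dropout(f, cfg.dropout, rng, training),
                             self.ln2_g, self.ln2_b)


class DeformableTransformerEncoder:
    """Input projection + ``n_layers`` deformable encoder blocks."""

    def __init__(self, d_in: int, cfg: EncoderConfig):
        rng = np.random.default_rng(cfg.seed)
        self.d_in = int(d_in)
        self.cfg = cfg
        self.input_proj = Linear(d_in, cfg.d_enc, rng)
        self.layers = [DeformableAttentionLayer(cfg, rng)
                       for _ in range(cfg.n_layers)]

    def params(self) -> list[Tensor]:
        ps = self.input_proj.params()
        for layer in self.layers:
            ps.extend(layer.params())
        return ps

    def forward_tokens(self, tokens: Tensor, coords: np.ndarray,
                       grid_shape: tuple[int, int], training: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        cols = np.asarray(coords)[:, 0]
        rows = np.asarray(coords)[:, 1]
        ref = ad.constant(make_reference_points(grid_shape, coords=coords))
        x = self.input_proj(tokens)
        for layer in self.layers:
            x = layer.forward(x, rows, cols, grid_shape, ref,
                              training=training, rng=rng)
        return x

    # -- serialization ----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def save(self, path: str | Path) -> None:
        arrays = self.state_arrays()
        arrays["_config"] = np.frombuffer(
            json.dumps({"d_in": self.d_in, **asdict(self.cfg)}).encode(),
            dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DeformableTransformerEncoder":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["_config"]).decode())
            d_in = meta.pop("d_in")
            enc = cls(d_in, EncoderConfig(**meta))
            for i, p in enumerate(enc.params()):
                saved = npz[f"p{i}"]
                if saved.shape != p.data.shape:
                    raise ConfigurationError(
                        f"checkpoint shape mismatch at parameter {i}")
                p.data = saved.astype(np.float64)
        return enc


def project_tokens(bag: FeatureBag, cfg: EncoderConfig,
                   encoder: DeformableTransformerEncoder | None = None
                   ) -> GridTensorState:
    """Linearly project bag tokens to d_enc and scatter them onto the grid."""
    if encoder is None:
        encoder = DeformableTransformerEncoder(bag.d, cfg)
    projected = encoder.input_proj(ad.constant(bag.tokens)).data
    cols, rows = bag.coords[:, 0], bag.coords[:, 1]
    n_rows, n_cols = bag.grid_shape
    value_map = np.zeros((n_rows, n_cols, cfg.d_enc))
    value_map[rows, cols] = projected
    validity = np.zeros((n_rows, n_cols), dtype=bool)
    validity[rows, cols] = True
    ref = make_reference_points(bag.grid_shape, coords=bag.coords)
    return GridTensorState(value_map, validity, ref, rows, cols)


def deformable_self_attention(state: GridTensorState, queries: np.ndarray,
                              cfg: EncoderConfig,
                              layer: DeformableAttentionLayer | None = None
                              ) -> np.ndarray:
    """Apply one deformable self-attention pass (no residual/FFN) on a state."""
    if layer is None:
        layer = DeformableAttentionLayer(cfg, np.random.default_rng(cfg.seed))
    queries = np.asarray(queries, dtype=np.float64)
    if queries.shape != (len(state.rows), cfg.d_enc):
        raise ConfigurationError(
            f"queries must be ({len(state.rows)}, {cfg.d_enc}), "
            f"got {queries.shape}")
    grid_shape = state.validity_mask.shape
    # self-attention: the queries are also the value stream source
    out = layer.attention(ad.constant(queries), state.rows, state.cols,
                          grid_shape, ad.constant(state.reference_points))
    return out.data


def encode(bag: FeatureBag, cfg: EncoderConfig,
           encoder: DeformableTransformerEncoder | None = None) -> FeatureBag:
    """Contextually aggregate a (position-embedded) bag over its grid.

    Returns a bag with the same N and coords and token dimension ``d_enc``.
    With ``n_layers=0`` this is the identity on the projected tokens.
    """
    if encoder is None:
        encoder = DeformableTransformerEncoder(bag.d, cfg)
    out = encoder.forward_tokens(ad.constant(bag.tokens), bag.coords,
                                 bag.grid_shape)
    return bag.with_tokens(out.data)
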