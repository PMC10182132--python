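"""Dual-stream MIL aggregation head.

Stream 1 (local): an instance classifier g_inst scores every token; the
critical instance is the argmax (ties broken by lowest index) and its score
is c_max.  Stream 2 (global): a simplified one-query attention — only
scores between the critical token's query and every token's query are
computed — pools value projections into a slide feature f_slide, scored by
g_slide as c_slide.  The fused slide score is the arithmetic mean
c = (c_max + c_slide) / 2.  All scores are sigmoid probabilities so c is a
probability and can be thresholded directly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .encoder import DeformableTransformerEncoder, EncoderConfig, Linear
from .errors import DataError
from .features import FeatureBag


@dataclass
class MILOutput:
    """Full output of one slide-level forward pass."""

    instance_scores: np.ndarray
    critical_index: int
    attention: np.ndarray
    f_slide: np.ndarray
    c_max: float
    c_slide: float
    c: float
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.instance_scores = np.asarray(self.instance_scores, dtype=np.float64)
        self.attention = np.asarray(self.attention, dtype=np.float64)
        if not 0 <= self.critical_index < len(self.instance_scores):
            raise DataError("critical_index out of range")
        if abs(self.attention.sum() - 1.0) > 1e-6 or (self.attention < 0).any():
            raise DataError("attention must be non-negative and sum to 1")
        if not 0.0 <= self.c <= 1.0:
            raise DataError("fused score must lie in [0, 1]")

    def save(self, outdir: str | Path, slide_id: str = "slide") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        jpath = outdir / f"{slide_id}.mil.json"
        cpath = outdir / f"{slide_id}.mil.csv"
        jpath.write_text(json.dumps({
            "slide_id": slide_id, "critical_index": int(self.critical_index),
            "c_max": self.c_max, "c_slide": self.c_slide, "c": self.c,
        }, indent=2))
        with open(cpath, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["idx", "col", "row", "instance_score", "attention"])
            for i, (s, a) in enumerate(zip(self.instance_scores, self.attention)):
                x, y = (self.coords[i] if self.coords is not None else (-1, -1))
                writer.writerow([i, int(x), int(y), repr(float(s)), repr(float(a))])
        return {"json": jpath, "csv": cpath}


class MILHeadParams:
    """Learned parameters of the dual-stream head.

    The query map Q is linear -> ReLU -> linear, the value map V linear,
    following the dual-stream MIL lineage; g_inst and g_slide are linear +
    sigmoid.  Attention logits are inner products of queries with the
    critical query, divided by sqrt(d_q) when ``scale_logits`` is set.
    """

    def __init__(self, d_in: int, d_q: int = 128, d_v: int = 128,
                 scale_logits: bool = True, seed: int = 0):
        if d_q < 1 or d_v < 1:
            raise DataError("d_q and d_v must be >= 1")
        rng = np.random.default_rng(seed)
        self.d_in, self.d_q, self.d_v = int(d_in), int(d_q), int(d_v)
        self.scale_logits = bool(scale_logits)
        self.g_inst = Linear(d_in, 1, rng)
        self.q1 = Linear(d_in, d_q, rng)
        self.q2 = Linear(d_q, d_q, rng)
        self.v_proj = Linear(d_in, d_v, rng)
        self.g_slide = Linear(d_v, 1, rng)

    def params(self) -> list[Tensor]:
        ps = []
        for lin in (self.g_inst, self.q1, self.q2, self.v_proj, self.g_slide):
            ps.extend(lin.params())
        return ps

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        arrays["_config"] = np.frombuffer(json.dumps({
            "d_in": self.d_in, "d_q": self.d_q, "d_v": self.d_v,
            "scale_logits": self.scale_logits}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MILHeadParams":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["_config"]).decode())
            head = cls(**meta)
            for i, p in enumerate(head.params()):
                p.data = npz[f"p{i}"].astype(np.float64)
        return head


# -- differentiable forward (training path) -------------------------------

def _forward_t(tokens: Tensor, params: MILHeadParams) -> dict:
    scores = params.g_inst(tokens).sigmoid().reshape(-1)
    crit = int(np.argmax(scores.data))  # lowest index wins ties (np.argmax)
    c_max = scores[crit]
    q = params.q2(params.q1(tokens).relu())
    q_crit = q[crit]
    logits = q @ q_crit
    if params.scale_logits:
        logits = logits * (1.0 / math.sqrt(params.d_q))
    attention = ad.softmax(logits, axis=-1)
    values = params.v_proj(tokens)
    f_slide = attention @ values
    c_slide = params.g_slide(f_slide).sigmoid().reshape(())
    c = (c_max + c_slide) * 0.5
    return {"instance_scores": scores, "critical_index": crit, "c_max": c_max,
            "attention": attention, "f_slide": f_slide, "c_slide": c_slide,
            "c": c}


# -- spec operation surface (NumPy in / NumPy out) -------------------------

def score_instances(bag: FeatureBag, params: MILHeadParams) -> np.ndarray:
    """One sigmoid probability per token, c_idx = g_inst(f_idx)."""
    return params.g_inst(ad.constant(bag.tokens)).sigmoid().data.reshape(-1)


def select_critical(scores: np.ndarray) -> tuple[int, float]:
    """Argmax instance; ties broken by lowest index."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise DataError("cannot select the critical instance of an empty bag")
    idx = int(np.argmax(scores))
    return idx, float(scores[idx])


def mil_attention(tokens: np.ndarray, critical_index: int,
                  params: MILHeadParams) -> tuple[np.ndarray, np.ndarray]:
    """Attention of every token against the critical query; pooled f_slide."""
    tokens_t = ad.constant(np.asarray(tokens, dtype=np.float64))
    if not 0 <= critical_index < tokens_t.data.shape[0]:
        raise DataError("critical_index out of range")
    q = params.q2(params.q1(tokens_t).relu())
    logits = q @ q[critical_index]
    if params.scale_logits:
        logits = logits * (1.0 / math.sqrt(params.d_q))
    attention = ad.softmax(logits, axis=-1)
    f_slide = attention @ params.v_proj(tokens_t)
    return attention.data, f_slide.data


def slide_score(f_slide: np.ndarray, params: MILHeadParams) -> float:
    """Global-level sigmoid probability c_slide = g_slide(f_slide)."""
    return float(params.g_slide(ad.constant(f_slide)).sigmoid().data.reshape(()))


def fuse_scores(c_max: float, c_slide: float) -> float:
    """Fused slide score c = (c_max + c_slide) / 2."""
    if not (0.0 <= c_max <= 1.0 and 0.0 <= c_slide <= 1.0):
        raise DataError("c_max and c_slide must lie in [0, 1]")
    return 0.5 * (c_max + c_slide)


def forward(bag: FeatureBag, encoder_cfg: EncoderConfig,
            params: MILHeadParams,
            encoder: DeformableTransformerEncoder | None = None) -> MILOutput:
    """Full slide pass: encode, score instances, attend, score slide, fuse."""
    if encoder is None:
        encoder = DeformableTransformerEncoder(bag.d, encoder_cfg)
    enc_tokens = encoder.forward_tokens(ad.constant(bag.tokens), bag.coords,
                                        bag.grid_shape)
    out = _forward_t(enc_tokens, params)
    return MILOutput(
        instance_scores=out["instance_scores"].data,
        critical_index=out["critical_index"],
        attention=out["attention"].data,
        f_slide=out["f_slide"].data,
        c_max=float(out["c_max"].data),
        c_slide=float(out["c_slide"].data),
        c=float(out["c"].data),
        coords=bag.coords,
    )
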