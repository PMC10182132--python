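"""Inference-only NumPy CNN backbones for patch feature extraction.

Two topologies are provided:

* ``tiny_test_cnn`` — a three-layer strided conv net with a 32-d output,
  deterministic given its seed; the default extractor for synthetic runs.
* ``resnet50_imagenet_topology`` — the standard ResNet-50 layout with the
  final classification layer removed, so the output of global average
  pooling is a 2048-d feature vector.  Weights are He-initialized from the
  seed (or loaded from an ``.npz``); no download is involved.

Convolutions are im2col + matmul in float32; batch norm layers start at
identity scaling (gamma=1, beta=0, running stats 0/1), which is exact for a
randomly initialized topology check.
"""

from __future__ import annotations

import numpy as np

# ImageNet channel statistics used to standardize patches after /255 scaling.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def preprocess_patches(patches: np.ndarray) -> np.ndarray:
    """uint8/float HWC patches -> standardized float32 NCHW batch."""
    x = np.asarray(patches)
    if x.ndim == 3:
        x = x[None]
    x = x.astype(np.float32)
    if x.max(initial=0.0) > 1.5:  # uint8-scaled input
        x = x / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> tuple:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, kh, kw),
        (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return cols, ho, wo


def conv2d(x: np.ndarray, weight: np.ndarray, stride: int = 1, pad: int = 0,
           bias: np.ndarray | None = None) -> np.ndarray:
    """NCHW convolution; weight is (out_c, in_c, kh, kw)."""
    oc, ic, kh, kw = weight.shape
    n = x.shape[0]
    cols, ho, wo = _im2col(x, kh, kw, stride, pad)
    out = cols @ weight.reshape(oc, -1).T
    if bias is not None:
        out += bias
    return out.reshape(n, ho, wo, oc).transpose(0, 3, 1, 2)


def maxpool2d(x: np.ndarray, k: int, stride: int, pad: int = 0) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                   constant_values=-np.inf)
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, k, k),
        (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
    )
    return windows.max(axis=(4, 5))


def _he_conv(rng: np.random.Generator, oc: int, ic: int, k: int) -> np.ndarray:
    fan_in = ic * k * k
    return rng.normal(0.0, np.sqrt(2.0 / fan_in),
                      size=(oc, ic, k, k)).astype(np.float32)


class TinyTestCNN:
    """Three strided 3x3 conv + ReLU stages, global average pool, linear head."""

    name = "tiny_test_cnn"

    def __init__(self, output_dim: int = 32, seed: int = 0,
                 weights: dict[str, np.ndarray] | None = None):
        self.output_dim = int(output_dim)
        channels = [3, 8, 16, 32]
        if weights is None:
            rng = np.random.default_rng(seed)
            weights = {}
            for i in range(3):
                weights[f"conv{i}"] = _he_conv(rng, channels[i + 1], channels[i], 3)
            weights["head_w"] = rng.normal(
                0.0, np.sqrt(1.0 / channels[-1]),
                size=(channels[-1], self.output_dim)).astype(np.float32)
        self.weights = weights

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        # samples are processed one at a time so outputs are bit-identical
        # regardless of how patches are batched
        x = preprocess_patches(patches)
        return np.concatenate([self._forward_one(x[i:i + 1])
                               for i in range(x.shape[0])], axis=0)

    def _forward_one(self, x: np.ndarray) -> np.ndarray:
        for i in range(3):
            x = conv2d(x, self.weights[f"conv{i}"], stride=2, pad=1)
            x = np.maximum(x, 0.0)
        feat = x.mean(axis=(2, 3))
        return (feat @ self.weights["head_w"]).astype(np.float64)


class ResNet50Topology:
    """ResNet-50 feature topology (classification layer removed, 2048-d out).

    Layout: 7x7/2 stem conv, 3x3/2 max pool, bottleneck stages of depth
    (3, 4, 6, 3) with widths (256, 512, 1024, 2048), global average pool.
    Batch norms are identity at initialization, so the forward pass is a
    plain conv/ReLU composition.
    """

    name = "resnet50_imagenet_topology"
    output_dim = 2048

    STAGES = ((3, 64, 256, 1), (4, 128, 512, 2), (6, 256, 1024, 2),
              (3, 512, 2048, 2))

    def __init__(self, seed: int = 0, weights: dict[str, np.ndarray] | None = None):
        if weights is None:
            rng = np.random.default_rng(seed)
            weights = {"stem": _he_conv(rng, 64, 3, 7)}
            in_c = 64
            for si, (depth, mid, out_c, _stride) in enumerate(self.STAGES):
                for bi in range(depth):
                    p = f"s{si}b{bi}"
                    weights[f"{p}c1"] = _he_conv(rng, mid, in_c, 1)
                    weights[f"{p}c2"] = _he_conv(rng, mid, mid, 3)
                    weights[f"{p}c3"] = _he_conv(rng, out_c, mid, 1)
                    if bi == 0:
                        weights[f"{p}proj"] = _he_conv(rng, out_c, in_c, 1)
                    in_c = out_c
        self.weights = weights

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        x = preprocess_patches(patches)
        return np.concatenate([self._forward_one(x[i:i + 1])
                               for i in range(x.shape[0])], axis=0)

    def _forward_one(self, x: np.ndarray) -> np.ndarray:
        w = self.weights
        x = np.maximum(conv2d(x, w["stem"], stride=2, pad=3), 0.0)
        x = maxpool2d(x, 3, 2, pad=1)
        for si, (depth, _mid, _out_c, stride) in enumerate(self.STAGES):
            for bi in range(depth):
                p = f"s{si}b{bi}"
                s = stride if bi == 0 else 1
                y = np.maximum(conv2d(x, w[f"{p}c1"], stride=1), 0.0)
                y = np.maximum(conv2d(y, w[f"{p}c2"], stride=s, pad=1), 0.0)
                y = conv2d(y, w[f"{p}c3"], stride=1)
                sc = conv2d(x, w[f"{p}proj"], stride=s) if bi == 0 else x
                x = np.maximum(y + sc, 0.0)
        return x.mean(axis=(2, 3)).astype(np.float64)
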