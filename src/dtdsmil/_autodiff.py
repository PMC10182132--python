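"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the DT-DSMIL model needs: broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions, indexing/reshaping,
a grid scatter, and bilinear sampling with gradients with respect to both the
value map and the (learned, continuous) sampling locations.  Everything runs
in float64 so repeated runs under a fixed seed are bit-identical.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf as _np_erf

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "concat",
    "softmax",
    "gelu",
    "layer_norm",
    "scatter_grid",
    "bilinear_sample_grid",
    "dropout",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        a, b = self, other

        def bwd(g):
            ga, gb = None, None
            if a.data.ndim == 1 and b.data.ndim == 2:
                ga = g @ b.data.T
                gb = np.outer(a.data, g)
            elif a.data.ndim == 2 and b.data.ndim == 1:
                ga = np.outer(g, b.data)
                gb = a.data.T @ g
            elif a.data.ndim == 1 and b.data.ndim == 1:
                ga = g * b.data
                gb = g * a.data
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
                ga = _unbroadcast(ga, a.data.shape)
                gb = _unbroadcast(gb, b.data.shape)
            if a.requires_grad:
                a._accum(ga)
            if b.requires_grad:
                b._accum(gb)

        out._backward = bwd
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0.0))
        return out

    def erf(self):
        out = Tensor(_np_erf(self.data), parents=(self,))
        out._backward = lambda g: self._accum(
            g * (2.0 / math.sqrt(math.pi)) * np.exp(-self.data ** 2)
        )
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - np.max(x.data, axis=axis, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-form) Gaussian error linear unit."""
    return x * 0.5 * ((x * (1.0 / math.sqrt(2.0))).erf() + 1.0)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gamma + beta


def scatter_grid(tokens: Tensor, rows: np.ndarray, cols: np.ndarray,
                 grid_shape: tuple[int, int]) -> Tensor:
    """Place token rows into an (n_rows, n_cols, d) map; empty cells zero."""
    n_rows, n_cols = grid_shape
    d = tokens.data.shape[1]
    vm = np.zeros((n_rows, n_cols, d))
    vm[rows, cols] = tokens.data
    out = Tensor(vm, parents=(tokens,))
    out._backward = lambda g: tokens._accum(g[rows, cols])
    return out


def _bilinear_parts(points: np.ndarray, n_rows: int, n_cols: int):
    gx = points[:, 0] * n_cols - 0.5
    gy = points[:, 1] * n_rows - 0.5
    x0 = np.floor(gx).astype(int)
    y0 = np.floor(gy).astype(int)
    fx = gx - x0
    fy = gy - y0
    corners = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy, xx = y0 + dy, x0 + dx
        valid = (yy >= 0) & (yy < n_rows) & (xx >= 0) & (xx < n_cols)
        wy = fy if dy == 1 else 1.0 - fy
        wx = fx if dx == 1 else 1.0 - fx
        corners.append((yy.clip(0, n_rows - 1), xx.clip(0, n_cols - 1),
                        valid, wy * wx, dy, dx))
    return corners, fx, fy


def bilinear_sample_grid(value_map: Tensor, points: Tensor) -> Tensor:
    """Bilinearly sample an (R, C, d) map at M normalized (x, y) points.

    Coordinates are normalized to (0, 1) with cell (r, c) centered at
    ((c + 0.5)/C, (r + 0.5)/R).  Locations outside the grid contribute zeros.
    Differentiable in both the map values and the point coordinates.
    """
    R, C, d = value_map.data.shape
    pts = points.data
    corners, fx, fy = _bilinear_parts(pts, R, C)
    vals = []
    out_data = np.zeros((pts.shape[0], d))
    for yy, xx, valid, w, dy, dx in corners:
        v = value_map.data[yy, xx] * valid[:, None]
        vals.append(v)
        out_data += w[:, None] * v
    out = Tensor(out_data, parents=(value_map, points))

    def bwd(g):
        if value_map.requires_grad:
            gm = np.zeros_like(value_map.data)
            for (yy, xx, valid, w, dy, dx) in corners:
                np.add.at(gm, (yy, xx), (w * valid)[:, None] * g)
            value_map._accum(gm)
        if points.requires_grad:
            v00, v01, v10, v11 = vals
            dfx = ((1 - fy)[:, None] * (v01 - v00) + fy[:, None] * (v11 - v10))
            dfy = ((1 - fx)[:, None] * (v10 - v00) + fx[:, None] * (v11 - v01))
            gp = np.stack([
                (g * dfx).sum(axis=1) * C,
                (g * dfy).sum(axis=1) * R,
            ], axis=1)
            points._accum(gp)

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
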