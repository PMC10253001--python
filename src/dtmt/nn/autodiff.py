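"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operator set the segmentation networks and
losses need: elementwise arithmetic, |x|, powers, reductions, sigmoid/ReLU,
2x2 max-pooling, nearest-neighbour x2 upsampling, channel concatenation and
stride-1 "same" 2D convolution (im2col + BLAS matmul).  Graphs are pruned
eagerly: a node whose parents carry no gradient requirement stores neither
parents nor a backward rule, so teacher forward passes (frozen parameters)
build no graph at all.

Arrays are float32 by default; every rule is dtype-agnostic so gradient
checking can run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "absolute",
    "concat",
    "conv2d",
    "instance_norm",
    "maxpool2",
    "mean",
    "relu",
    "sigmoid",
    "tensor_sum",
    "upsample2",
]


def _coerce(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """A numpy array with an optional gradient and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    # make numpy defer mixed ndarray-Tensor arithmetic to our operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = _coerce(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad += g

    # -- autodiff -------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is not None:
                node._vjp(node.grad)
                # free graph references as we go
                node._vjp = None
                node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        a._accumulate(g)
        b._accumulate(g)

    return Tensor._result(a.data + b.data, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        a._accumulate(g * b.data)
        b._accumulate(g * a.data)

    return Tensor._result(a.data * b.data, (a, b), vjp)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        a._accumulate(g / b.data)
        b._accumulate(-g * a.data / (b.data * b.data))

    return Tensor._result(a.data / b.data, (a, b), vjp)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)

    def vjp(g):
        a._accumulate(g * p * np.power(a.data, p - 1.0))

    return Tensor._result(np.power(a.data, p), (a,), vjp)


def absolute(a) -> Tensor:
    a = _as_tensor(a)

    def vjp(g):
        a._accumulate(g * np.sign(a.data))

    return Tensor._result(np.abs(a.data), (a,), vjp)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def vjp(g):
        a._accumulate(g * mask)

    return Tensor._result(a.data * mask, (a,), vjp)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    y = np.empty_like(a.data)
    pos = a.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    y[~pos] = e / (1.0 + e)

    def vjp(g):
        a._accumulate(g * y * (1.0 - y))

    return Tensor._result(y, (a,), vjp)


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def tensor_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor._result(out, (a,), vjp)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def vjp(g):
        a._accumulate(g.reshape(a.data.shape))

    return Tensor._result(a.data.reshape(shape), (a,), vjp)


def concat(parts, axis: int = 1) -> Tensor:
    parts = [_as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(g[tuple(sl)])

    return Tensor._result(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), vjp)


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def maxpool2(a) -> Tensor:
    a = _as_tensor(a)
    n, c, h, w = a.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    v = (
        a.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        z = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(z, idx[..., None], g[..., None], axis=-1)
        ga = (
            z.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        a._accumulate(ga)

    return Tensor._result(out, (a,), vjp)


def upsample2(a) -> Tensor:
    """Nearest-neighbour x2 upsampling of (N, C, H, W)."""
    a = _as_tensor(a)
    n, c, h, w = a.data.shape
    out = np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3)

    def vjp(g):
        a._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._result(out, (a,), vjp)


def instance_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Fused per-sample, per-channel normalisation with affine parameters.

    x: (N, C, H, W); gamma, beta: (1, C, 1, 1).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def vjp(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3), keepdims=True))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
        if x.requires_grad:
            gh = g * gamma.data
            gx = inv * (gh - gh.mean(axis=(2, 3), keepdims=True)
                        - xhat * np.mean(gh * xhat, axis=(2, 3), keepdims=True))
            x._accumulate(gx)

    return Tensor._result(out, (x, gamma, beta), vjp)


def _pad_nhwc(x: np.ndarray, p: int) -> np.ndarray:
    """NCHW -> padded NHWC (one contiguous copy)."""
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
    if p:
        xt = np.pad(xt, ((0, 0), (p, p), (p, p), (0, 0)))
    return xt


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, k*k*C) columns, built by k*k block copies."""
    n, c, h, wd = x.shape
    p = k // 2
    xp = _pad_nhwc(x, p)  # (N, H+2p, W+2p, C)
    if k == 1:
        return xp.reshape(n * h * wd, c)
    cols = np.empty((n, h, wd, k * k, c), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, :, di * k + dj, :] = xp[:, di:di + h, dj:dj + wd, :]
    return cols.reshape(n * h * wd, k * k * c)


def _conv2d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    """Same-padded stride-1 correlation; returns (y, cache-for-weight-grad).

    Two equivalent schemes, chosen by memory traffic: im2col + GEMM when the
    layer widens (O >= C), or one GEMM over the padded plane followed by k*k
    shifted adds when it narrows (O < C, the costly decoder convs).
    """
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    if k > 1 and o < c:
        p = k // 2
        hp, wp = h + 2 * p, wd + 2 * p
        xp = _pad_nhwc(x, p)
        wmat = w.transpose(1, 2, 3, 0).reshape(c, k * k * o)
        yfull = (xp.reshape(-1, c) @ wmat).reshape(n, hp, wp, k * k, o)
        y = np.zeros((n, h, wd, o), dtype=yfull.dtype)
        for di in range(k):
            for dj in range(k):
                y += yfull[:, di:di + h, dj:dj + wd, di * k + dj, :]
        cache = ("plane", xp)
    else:
        cols = _im2col(x, k)
        wmat = w.transpose(0, 2, 3, 1).reshape(o, k * k * c)
        y = (cols @ wmat.T).reshape(n, h, wd, o)
        cache = ("cols", cols)
    if b is not None:
        y += b
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)), cache


def _conv2d_weight_grad(cache, gy: np.ndarray, wshape) -> np.ndarray:
    o, c, k, _ = wshape
    n, _, h, wd = gy.shape
    mode, stored = cache
    gy_nhwc = np.ascontiguousarray(gy.transpose(0, 2, 3, 1))
    if mode == "cols":
        gw = gy_nhwc.reshape(n * h * wd, o).T @ stored  # (O, k*k*C)
        return np.ascontiguousarray(gw.reshape(o, k, k, c).transpose(0, 3, 1, 2))
    # exact transpose of the shifted-add forward
    hp, wp = stored.shape[1], stored.shape[2]
    gfull = np.zeros((n, hp, wp, k * k, o), dtype=gy.dtype)
    for di in range(k):
        for dj in range(k):
            gfull[:, di:di + h, dj:dj + wd, di * k + dj, :] = gy_nhwc
    gw = stored.reshape(-1, c).T @ gfull.reshape(n * hp * wp, k * k * o)
    return np.ascontiguousarray(gw.reshape(c, k, k, o).transpose(3, 0, 1, 2))


def conv2d(x, weight, bias=None) -> Tensor:
    """Stride-1 "same"-padded 2D correlation.

    x: (N, C, H, W); weight: (O, C, k, k) with odd k; bias: (O,) or None.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    bias = _as_tensor(bias) if bias is not None else None
    y, cache = _conv2d_raw(x.data, weight.data,
                           bias.data if bias is not None else None)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def vjp(g):
        if weight.requires_grad:
            weight._accumulate(_conv2d_weight_grad(cache, g, weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation with the flipped, channel-transposed kernel
            wt = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            gx, _ = _conv2d_raw(g, wt, None)
            x._accumulate(gx)

    return Tensor._result(y, parents, vjp)
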