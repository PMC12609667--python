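"""A compact reverse-mode automatic-differentiation engine over numpy.

The segmentation network, its building blocks and the training loop are all
expressed in terms of this module.  It provides exactly the primitives the
architecture needs -- strided 2-D convolution (im2col + BLAS matmul), batch
normalization, ReLU/sigmoid, pixel shuffle, bilinear ``grid_sample`` with
gradients w.r.t. both input and sampling grid, max pooling, global average
pooling, the fixed orthonormal Haar analysis/synthesis pair, a log-softmax --
plus `Module`/`Adam` plumbing.  Everything is float32 NCHW.

It is intentionally small: no graph optimization, no broadcasting beyond what
the layers use, eager shape checks.  Gradient correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import wavelet as wv

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (eval-mode forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        # float32 by default (the network path); explicit float64 *arrays*
        # keep their precision so loss fixtures can be checked to tight
        # tolerances — Python scalars stay float32 to avoid silently
        # promoting whole computation graphs.
        # note: np.ascontiguousarray would promote 0-d scalars to 1-d
        # np scalars (ufunc/reduction results on 0-d) count as arrays here;
        # plain Python floats do not
        keep64 = (isinstance(data, (np.ndarray, np.floating))
                  and np.asarray(data).dtype == np.float64)
        data = np.asarray(data)
        if not keep64:
            data = data.astype(np.float32, copy=False)
        self.data = data if data.flags["C_CONTIGUOUS"] else np.ascontiguousarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return self.data.item()

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core ------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(other))

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if req:
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # overflow-safe logistic
    data = np.empty_like(a.data)
    pos = a.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    data[~pos] = ex / (1.0 + ex)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def permute(a, axes: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    data = np.ascontiguousarray(a.data.transpose(axes))
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.ascontiguousarray(g.transpose(inv)))

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis."""
    a = as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = a.data[idx].copy()

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# structured ops: conv / pooling / pixel shuffle / grid sample / wavelets
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with OIkk weights."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    s = int(stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]  # n,c,ho,wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    y = cols @ wmat.T
    if b is not None:
        b = as_tensor(b)
        y += b.data
    data = y.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            gcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += gcols[:, :, :, :, i, j]
            if padding:
                gxp = gxp[:, :, padding : padding + h, padding : padding + wd]
            x._accumulate(gxp)

    return _make(np.ascontiguousarray(data), parents, backward)


def max_pool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        mode="constant",
        constant_values=-np.inf,
    )
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        ki, kj = np.unravel_index(idx, (kernel, kernel))
        ni, cidx, hi, wi = np.indices(idx.shape, sparse=False)
        rows = hi * stride + ki
        colsi = wi * stride + kj
        np.add.at(gxp, (ni, cidx, rows, colsi), g)
        x._accumulate(gxp[:, :, padding : padding + h, padding : padding + w])

    return _make(np.ascontiguousarray(data), (x,), backward)


def global_avg_pool(x) -> Tensor:
    """GAP over the spatial axes, keepdims (N, C, 1, 1)."""
    return tmean(x, axis=(2, 3), keepdims=True)


def pixel_shuffle(x, r: int) -> Tensor:
    """(N, C*r^2, H, W) -> (N, C, H*r, W*r)."""
    x = as_tensor(x)
    n, crr, h, w = x.shape
    if crr % (r * r):
        raise ValueError(f"channels {crr} not divisible by r^2={r * r}")
    c = crr // (r * r)
    y = reshape(x, (n, c, r, r, h, w))
    y = permute(y, (0, 1, 4, 2, 5, 3))  # n, c, h, r, w, r
    return reshape(y, (n, c, h * r, w * r))


def grid_sample(x, grid) -> Tensor:
    """Bilinear sampling with border clamping.

    ``grid`` is (N, Ho, Wo, 2) with coordinates in [-1, 1], last axis (gx, gy),
    half-pixel-center convention (``px = ((gx + 1) * W - 1) / 2``).  Gradients
    flow to both the input values and the grid coordinates; clamped
    coordinates get zero coordinate-gradient.
    """
    x, grid = as_tensor(x), as_tensor(grid)
    n, c, h, w = x.shape
    gx = (grid.data[..., 0] + 1.0) * w / 2.0 - 0.5
    gy = (grid.data[..., 1] + 1.0) * h / 2.0 - 0.5
    inx = (gx >= 0.0) & (gx <= w - 1.0)
    iny = (gy >= 0.0) & (gy <= h - 1.0)
    px = np.clip(gx, 0.0, w - 1.0)
    py = np.clip(gy, 0.0, h - 1.0)
    x0 = np.floor(px).astype(np.int64)
    y0 = np.floor(py).astype(np.int64)
    x0 = np.minimum(x0, w - 2) if w > 1 else np.zeros_like(x0)
    y0 = np.minimum(y0, h - 2) if h > 1 else np.zeros_like(y0)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (px - x0).astype(np.float32)
    fy = (py - y0).astype(np.float32)
    flat = x.data.reshape(n, c, h * w)

    def gather(yi, xi):
        # (n, ho, wo) index maps -> (n, c, ho, wo)
        lin = yi * w + xi
        return np.take_along_axis(flat, lin.reshape(n, 1, -1).repeat(c, axis=1), axis=2).reshape(
            n, c, *yi.shape[1:]
        )

    v00 = gather(y0, x0)
    v01 = gather(y0, x1)
    v10 = gather(y1, x0)
    v11 = gather(y1, x1)
    w00 = ((1 - fy) * (1 - fx))[:, None]
    w01 = ((1 - fy) * fx)[:, None]
    w10 = (fy * (1 - fx))[:, None]
    w11 = (fy * fx)[:, None]
    data = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11

    def backward(g):
        if x.requires_grad:
            # np.add.at handles duplicate sample locations correctly
            ni = np.broadcast_to(np.arange(n)[:, None, None, None], (n, c) + y0.shape[1:])
            ci = np.broadcast_to(np.arange(c)[None, :, None, None], (n, c) + y0.shape[1:])
            gx4 = np.zeros((n, c, h, w), dtype=np.float32)
            for yi, xi, wt in ((y0, x0, w00), (y0, x1, w01), (y1, x0, w10), (y1, x1, w11)):
                yb = np.broadcast_to(yi[:, None], (n, c) + yi.shape[1:])
                xb = np.broadcast_to(xi[:, None], (n, c) + xi.shape[1:])
                np.add.at(gx4, (ni, ci, yb, xb), g * wt)
            x._accumulate(gx4)
        if grid.requires_grad:
            dfx = ((v01 - v00) * (1 - fy)[:, None] + (v11 - v10) * fy[:, None])
            dfy = ((v10 - v00) * (1 - fx)[:, None] + (v11 - v01) * fx[:, None])
            gpx = (g * dfx).sum(axis=1) * inx  # zero where clamped
            gpy = (g * dfy).sum(axis=1) * iny
            gg = np.stack([gpx * (w / 2.0), gpy * (h / 2.0)], axis=-1)
            grid._accumulate(gg.astype(np.float32))

    return _make(data.astype(np.float32), (x, grid), backward)


def identity_grid(n: int, ho: int, wo: int) -> np.ndarray:
    """Regular half-pixel-center sampling grid in [-1, 1], shape (n, ho, wo, 2)."""
    xs = (2.0 * (np.arange(wo) + 0.5) / wo - 1.0).astype(np.float32)
    ys = (2.0 * (np.arange(ho) + 0.5) / ho - 1.0).astype(np.float32)
    gx, gy = np.meshgrid(xs, ys)
    g = np.stack([gx, gy], axis=-1)
    return np.broadcast_to(g, (n, ho, wo, 2)).copy()


def upsample_bilinear(x, scale: int) -> Tensor:
    """Plain bilinear upsampling (half-pixel centers) via grid sampling."""
    x = as_tensor(x)
    n, _, h, w = x.shape
    grid = Tensor(identity_grid(n, h * scale, w * scale))
    return grid_sample(x, grid)


_HAAR = wv.haar_filter_bank()


def haar_dwt(x) -> Tensor:
    """Channel-concatenated Haar subbands (N, 4C, H/2, W/2), order LL, LH, HL, HH."""
    x = as_tensor(x)
    s = wv.hwt_decompose(x.data, _HAAR)
    data = s.concat_channels()

    def backward(g):
        if x.requires_grad:
            c = x.shape[1]
            sub = wv.SubbandSet(g[:, :c], g[:, c : 2 * c], g[:, 2 * c : 3 * c], g[:, 3 * c :])
            x._accumulate(wv.iwt_reconstruct(sub, _HAAR).astype(np.float32))

    return _make(data.astype(np.float32), (x,), backward)


def haar_iwt(x) -> Tensor:
    """Inverse of :func:`haar_dwt`: (N, 4C, H', W') -> (N, C, 2H', 2W')."""
    x = as_tensor(x)
    c4 = x.shape[1]
    if c4 % 4:
        raise ValueError("haar_iwt expects a channel count divisible by 4")
    c = c4 // 4
    sub = wv.SubbandSet(x.data[:, :c], x.data[:, c : 2 * c], x.data[:, 2 * c : 3 * c], x.data[:, 3 * c :])
    data = wv.iwt_reconstruct(sub, _HAAR)

    def backward(g):
        if x.requires_grad:
            s = wv.hwt_decompose(g, _HAAR)
            x._accumulate(s.concat_channels().astype(np.float32))

    return _make(data.astype(np.float32), (x,), backward)


def log_softmax(x, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse
    sm = np.exp(data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(data, (x,), backward)


def softmax(x, axis: int = 1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Minimal layer base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                yield name, v

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        expected = set(params)
        buffers: dict[str, tuple[Module, str]] = {}
        for m_name, m in _named_modules(self):
            for k, v in m.__dict__.items():
                if isinstance(v, np.ndarray) and k.startswith("running_"):
                    buffers[f"{m_name}{k}"] = (m, k)
        expected |= set(buffers)
        missing = expected - set(d)
        extra = set(d) - expected
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != d[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {d[name].shape}")
            p.data = np.ascontiguousarray(d[name], dtype=np.float32)
        for name, (m, k) in buffers.items():
            setattr(m, k, np.ascontiguousarray(d[name], dtype=np.float32))


def _named_modules(root: Module, prefix: str = "") -> Iterable[tuple[str, Module]]:
    yield prefix, root
    for k, v in root.__dict__.items():
        if isinstance(v, Module):
            yield from _named_modules(v, f"{prefix}{k}.")
        elif isinstance(v, (list, tuple)):
            for i, item in enumerate(v):
                if isinstance(item, Module):
                    yield from _named_modules(item, f"{prefix}{k}.{i}.")


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
              gain: float = 2.0) -> np.ndarray:
    """Kaiming-normal initialization: N(0, sqrt(gain / fan_in)).

    gain 2 is the ReLU-layer choice; purely linear layers use gain 1 so
    chains of them preserve activation variance.
    """
    return rng.normal(0.0, math.sqrt(gain / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None,
                 gain: float = 2.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in, gain),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(ch, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x):
        x = as_tensor(x)
        n, c, h, w = x.shape
        if self.training:
            mu = tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = tmean(mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            cnt = n * h * w
            unbiased = var.data.reshape(c) * (cnt / max(cnt - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c)).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
            xhat = mul(xc, power(var + self.eps, -0.5))
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - mu) * Tensor(1.0 / sd)
        g = reshape(self.weight, (1, c, 1, 1))
        b = reshape(self.bias, (1, c, 1, 1))
        return add(mul(xhat, g), b)


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ConvBNReLU(Sequential):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None, relu_tail: bool = True):
        layers = [Conv2d(in_ch, out_ch, kernel, stride, padding, bias=False, rng=rng), BatchNorm2d(out_ch)]
        if relu_tail:
            layers.append(ReLU())
        super().__init__(*layers)


class Adam:
    """Adam with L2 regularization folded into the gradient."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.99, 0.99), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


class ReduceLROnPlateau:
    """Halve (by `factor`) the optimizer lr when the monitored metric stalls."""

    def __init__(self, optimizer: Adam, mode: str = "max", factor: float = 0.5,
                 patience: int = 10, min_lr: float = 1e-6):
        self.opt = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best: float | None = None
        self.stale = 0

    def step(self, metric: float) -> bool:
        improved = (
            self.best is None
            or (self.mode == "max" and metric > self.best)
            or (self.mode == "min" and metric < self.best)
        )
        if improved:
            self.best = metric
            self.stale = 0
            return False
        self.stale += 1
        # a constant metric for patience+1 epochs triggers exactly one halving
        if self.stale >= self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.stale = 0
            return True
        return False
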