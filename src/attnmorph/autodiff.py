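"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core of the package: a small tape-based tensor type
plus exactly the differentiable operations the registration model needs —
3D convolution, nearest-neighbour upsampling, windowed box sums, trilinear
warping and the usual elementwise/reduction primitives.

Every public op here is *dual dispatch*: called on plain numpy arrays it
returns a plain numpy array (no graph is built), called on at least one
:class:`Tensor` it returns a Tensor wired into the tape.  Higher-level
modules (attention blocks, losses) are written once against these ops and
work both as cheap numpy evaluation and inside training graphs.

All Tensor data is float32; gradients are float32.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit


class Tensor:
    """Array node on the autodiff tape.

    Parameters
    ----------
    data : array_like
        Values; stored as float32.
    requires_grad : bool
        Mark as a leaf whose gradient should be accumulated.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        # interior nodes need grad if any parent does
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _parents
        )
        self._parents = tuple(_parents) if self.requires_grad else ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- backward pass -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in node._parents:
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                if parent.grad is None:
                    parent.grad = pg.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + pg
            if node is not self and node._parents:
                node.grad = None  # free interior gradients

    # -- operator overloads ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, idx):
        return getitem(self, idx)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def value_of(x) -> np.ndarray:
    """Underlying numpy array of a Tensor or array."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.add(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(
        a.data + b.data,
        _parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )
    return out


def mul(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.multiply(a, b)
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        _parents=(
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ),
    )


def div(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.divide(a, b)
    a, b = as_tensor(a), as_tensor(b)
    inv = 1.0 / b.data
    return Tensor(
        a.data * inv,
        _parents=(
            (a, lambda g: _unbroadcast(g * inv, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * a.data * inv * inv, b.data.shape)),
        ),
    )


def square(x):
    return mul(x, x)


def getitem(x, idx):
    if not is_tensor(x):
        return np.asarray(x)[idx]

    def vjp(g):
        out = np.zeros_like(x.data)
        out[idx] = g
        return out

    return Tensor(x.data[idx], _parents=((x, vjp),))


def reshape(x, shape):
    if not is_tensor(x):
        return np.reshape(x, shape)
    old = x.data.shape
    return Tensor(
        x.data.reshape(shape), _parents=((x, lambda g: g.reshape(old)),)
    )


def concat(xs: Sequence, axis: int = 0):
    if not any(is_tensor(x) for x in xs):
        return np.concatenate([np.asarray(x) for x in xs], axis=axis)
    ts = [as_tensor(x) for x in xs]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * ts[i].data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        _parents=tuple((ts[i], make_vjp(i)) for i in range(len(ts))),
    )


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(x):
    if not is_tensor(x):
        return expit(x)
    y = expit(x.data)
    return Tensor(y, _parents=((x, lambda g: g * y * (1.0 - y)),))


def relu(x):
    if not is_tensor(x):
        return np.maximum(x, 0)
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0.0), _parents=((x, lambda g: g * mask),))


def leaky_relu(x, slope: float = 0.2):
    if not is_tensor(x):
        return np.where(np.asarray(x) > 0, x, slope * np.asarray(x))
    mask = x.data > 0
    scale = np.where(mask, 1.0, slope).astype(np.float32)
    return Tensor(x.data * scale, _parents=((x, lambda g: g * scale),))


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def sum_all(x):
    if not is_tensor(x):
        return np.sum(x)
    shape = x.data.shape
    return Tensor(
        np.sum(x.data), _parents=((x, lambda g: np.broadcast_to(g, shape).copy()),)
    )


def mean_axes(x, axes: tuple, keepdims: bool = False):
    """Mean over the given axes."""
    if not is_tensor(x):
        return np.mean(x, axis=axes, keepdims=keepdims)
    n = int(np.prod([x.data.shape[a] for a in axes]))
    y = np.mean(x.data, axis=axes, keepdims=keepdims)

    def vjp(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return np.broadcast_to(g / n, x.data.shape).copy()

    return Tensor(y, _parents=((x, vjp),))


# ---------------------------------------------------------------------------
# linear maps over the channel axis (1x1x1 convolutions)
# ---------------------------------------------------------------------------

def channel_linear(x, w, b=None):
    """Apply ``y[o, ...] = sum_i w[o, i] * x[i, ...] (+ b[o])``.

    ``x`` has shape (C_in, *spatial); ``w`` is (C_out, C_in); ``b`` is
    (C_out,) or None.  Works for any number of trailing spatial axes.
    """
    if not (is_tensor(x) or is_tensor(w) or (b is not None and is_tensor(b))):
        y = np.tensordot(np.asarray(w), np.asarray(x), axes=([1], [0]))
        if b is not None:
            y = y + np.reshape(b, (-1,) + (1,) * (y.ndim - 1))
        return y
    x, w = as_tensor(x), as_tensor(w)
    y = np.tensordot(w.data, x.data, axes=([1], [0]))
    parents = [
        (x, lambda g: np.tensordot(w.data.T, g, axes=([1], [0]))),
        (
            w,
            lambda g: g.reshape(g.shape[0], -1) @ x.data.reshape(x.data.shape[0], -1).T,
        ),
    ]
    if b is not None:
        b = as_tensor(b)
        y = y + b.data.reshape((-1,) + (1,) * (y.ndim - 1))
        parents.append((b, lambda g: g.reshape(g.shape[0], -1).sum(axis=1)))
    return Tensor(y, _parents=tuple(parents))


# ---------------------------------------------------------------------------
# 3D convolution (kernel 3, padding 1, stride 1 or 2)
# ---------------------------------------------------------------------------

_K_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


def _out_extent(n: int, stride: int) -> int:
    # kernel 3, pad 1
    return (n - 1) // stride + 1


def conv3d(x, w, b=None, stride: int = 1):
    """3D convolution with 3x3x3 kernel, zero padding 1.

    ``x``: (C_in, D, H, W); ``w``: (C_out, C_in, 3, 3, 3); ``b``: (C_out,).
    stride 1 preserves the grid; stride 2 halves each axis (even extents).
    Implemented as 27 shifted-slice matrix products, which keeps the data
    movement to simple strided copies.
    """
    track = is_tensor(x) or is_tensor(w) or (b is not None and is_tensor(b))
    xd = value_of(x).astype(np.float32, copy=False)
    wd = value_of(w).astype(np.float32, copy=False)
    cin, d, h, wdim = xd.shape
    cout = wd.shape[0]
    od, oh, ow = (_out_extent(d, stride), _out_extent(h, stride),
                  _out_extent(wdim, stride))
    n = od * oh * ow
    xp = np.pad(xd, ((0, 0), (1, 1), (1, 1), (1, 1)))

    def x_slice(a, bb, c):
        return np.ascontiguousarray(
            xp[:, a : a + stride * od : stride, bb : bb + stride * oh : stride,
               c : c + stride * ow : stride]
        ).reshape(cin, n)

    y = np.zeros((cout, n), dtype=np.float32)
    for a, bb, c in _K_OFFSETS:
        y += wd[:, :, a, bb, c] @ x_slice(a, bb, c)
    if b is not None:
        y = y + value_of(b).reshape(-1, 1)
    y = y.reshape(cout, od, oh, ow)
    if not track:
        return y

    x_t = as_tensor(x)
    w_t = as_tensor(w)

    def vjp_x(g):
        g2 = g.reshape(cout, n)
        gxp = np.zeros_like(xp)
        for a, bb, c in _K_OFFSETS:
            gxp[:, a : a + stride * od : stride, bb : bb + stride * oh : stride,
                c : c + stride * ow : stride] += (
                wd[:, :, a, bb, c].T @ g2
            ).reshape(cin, od, oh, ow)
        return gxp[:, 1 : 1 + d, 1 : 1 + h, 1 : 1 + wdim]

    def vjp_w(g):
        g2 = g.reshape(cout, n)
        gw = np.empty_like(wd)
        for a, bb, c in _K_OFFSETS:
            gw[:, :, a, bb, c] = g2 @ x_slice(a, bb, c).T
        return gw

    parents = [(x_t, vjp_x), (w_t, vjp_w)]
    if b is not None:
        b_t = as_tensor(b)
        parents.append((b_t, lambda g: g.reshape(cout, -1).sum(axis=1)))
    return Tensor(y, _parents=tuple(parents))


def upsample2(x):
    """Nearest-neighbour x2 upsampling of a (C, D, H, W) feature map."""
    if not is_tensor(x):
        xd = np.asarray(x)
        return xd.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    c, d, h, w = x.data.shape
    y = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def vjp(g):
        return g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))

    return Tensor(y, _parents=((x, vjp),))


# ---------------------------------------------------------------------------
# windowed box sum (zero padding) — building block of the local CC loss
# ---------------------------------------------------------------------------

def _boxsum_np(x: np.ndarray, n: int) -> np.ndarray:
    # float64 accumulation for well-conditioned window statistics
    s = ndimage.uniform_filter(x.astype(np.float64), size=n, mode="constant") * (
        float(n) ** x.ndim
    )
    return s.astype(x.dtype, copy=False) if x.dtype == np.float64 else s


def boxsum(x, n: int):
    """Sum of each value's n^3 neighbourhood (zero padding outside the grid).

    The operator is linear and symmetric, hence self-adjoint: the VJP is a
    box sum of the incoming gradient.
    """
    if not is_tensor(x):
        return _boxsum_np(np.asarray(x, dtype=np.float64), n)
    y = _boxsum_np(x.data, n).astype(np.float32)
    return Tensor(y, _parents=((x, lambda g: _boxsum_np(g, n).astype(np.float32)),))


# ---------------------------------------------------------------------------
# trilinear warping (spatial transformer)
# ---------------------------------------------------------------------------

def _warp_nearest(m: np.ndarray, u: np.ndarray, boundary: str) -> np.ndarray:
    d, h, w = m.shape
    grid = np.indices((d, h, w), dtype=np.float64)
    coords = grid + u
    idx = np.rint(coords)
    if boundary == "zeros":
        inside = (
            (idx[0] >= 0)
            & (idx[0] < d)
            & (idx[1] >= 0)
            & (idx[1] < h)
            & (idx[2] >= 0)
            & (idx[2] < w)
        )
    ii = np.clip(idx[0], 0, d - 1).astype(np.intp)
    jj = np.clip(idx[1], 0, h - 1).astype(np.intp)
    kk = np.clip(idx[2], 0, w - 1).astype(np.intp)
    out = m[ii, jj, kk]
    if boundary == "zeros":
        out = np.where(inside, out, 0)
    return out


def warp3(m, u, mode: str = "trilinear", boundary: str = "border"):
    """Sample ``m`` at displaced positions p + u(p).

    ``m``: scalar grid (D, H, W); ``u``: displacement (3, D, H, W) in voxel
    units.  ``mode`` "trilinear" (differentiable w.r.t. both arguments) or
    "nearest" (label maps; no gradient).  ``boundary`` "border" clamps
    sample positions to the grid, "zeros" returns 0 outside.
    """
    if mode == "nearest":
        return _warp_nearest(value_of(m), value_of(u), boundary)
    track = is_tensor(m) or is_tensor(u)
    work = np.float32
    if not track and (value_of(m).dtype == np.float64
                      or value_of(u).dtype == np.float64):
        work = np.float64
    md = value_of(m).astype(work, copy=False)
    ud = value_of(u).astype(work, copy=False)
    d, h, w = md.shape
    dims = np.array([d, h, w], dtype=work)
    grid = np.indices((d, h, w), dtype=work)
    coords = grid + ud
    if boundary == "border":
        cl = np.stack([np.clip(coords[a], 0, dims[a] - 1) for a in range(3)])
        inbound = [
            (coords[a] > 0) & (coords[a] < dims[a] - 1) for a in range(3)
        ]  # where the clamp is inactive (gradient flows)
        corner_mask = None
    elif boundary == "zeros":
        cl = coords
        inbound = [np.ones_like(coords[a], dtype=bool) for a in range(3)]
        corner_mask = True
    else:
        raise ValueError(f"unknown boundary mode: {boundary}")

    i0 = np.floor(cl).astype(np.int64)
    t = cl - i0
    vals = {}
    weights1d = [(1.0 - t[a], t[a]) for a in range(3)]
    idx1d = [(i0[a], i0[a] + 1) for a in range(3)]
    out = np.zeros((d, h, w), dtype=work)
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                ii, jj, kk = idx1d[0][a], idx1d[1][b], idx1d[2][c]
                if corner_mask:
                    valid = (
                        (ii >= 0)
                        & (ii < d)
                        & (jj >= 0)
                        & (jj < h)
                        & (kk >= 0)
                        & (kk < w)
                    )
                else:
                    valid = None
                ic = np.clip(ii, 0, d - 1)
                jc = np.clip(jj, 0, h - 1)
                kc = np.clip(kk, 0, w - 1)
                v = md[ic, jc, kc]
                if valid is not None:
                    v = np.where(valid, v, 0.0)
                vals[(a, b, c)] = (v, ic, jc, kc, valid)
                out += weights1d[0][a] * weights1d[1][b] * weights1d[2][c] * v
    if not track:
        return out

    m_t = as_tensor(m) if is_tensor(m) else None
    u_t = as_tensor(u) if is_tensor(u) else None
    parents = []
    if m_t is not None:

        def vjp_m(g):
            gm = np.zeros_like(md)
            for a in (0, 1):
                for b in (0, 1):
                    for c in (0, 1):
                        v, ic, jc, kc, valid = vals[(a, b, c)]
                        wgt = (
                            weights1d[0][a] * weights1d[1][b] * weights1d[2][c] * g
                        )
                        if valid is not None:
                            wgt = np.where(valid, wgt, 0.0)
                        np.add.at(gm, (ic, jc, kc), wgt)
            return gm

        parents.append((m_t, vjp_m))
    if u_t is not None:

        def vjp_u(g):
            gu = np.zeros_like(ud)
            # d out / d t_axis, then mask where the border clamp is active
            for axis in range(3):
                dt = np.zeros((d, h, w), dtype=np.float32)
                for a in (0, 1):
                    for b in (0, 1):
                        for c in (0, 1):
                            sel = (a, b, c)[axis]
                            sign = 1.0 if sel == 1 else -1.0
                            wgt = sign
                            for other in range(3):
                                if other == axis:
                                    continue
                                wgt = wgt * weights1d[other][(a, b, c)[other]]
                            dt += wgt * vals[(a, b, c)][0]
                gu[axis] = g * dt * inbound[axis]
            return gu

        parents.append((u_t, vjp_u))
    return Tensor(out, _parents=tuple(parents))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
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
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
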