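"""Compact reverse-mode automatic differentiation over numpy arrays.

The training loop needs gradients through a fixed, small operator set: 3D
convolution, leaky ReLU, nearest-neighbor upsampling, channel
concatenation, pointwise arithmetic, clamped box-window sums (for the
local normalized cross-correlation), forward differences (for the
smoothness penalty), and trilinear resampling of a constant array at
flow-displaced coordinates (the spatial-transformer layer and the flow
aggregator).  This module implements exactly that set, CPU-only, with
convolutions lowered to im2col + BLAS matrix products.

Every op is validated by numeric gradient checks in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "no_grad", "grad_enabled"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _wrap(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    """A numpy array plus the closure that back-propagates into its parents."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value: np.ndarray, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.requires_grad = requires_grad

    # -- graph bookkeeping ---------------------------------------------------

    @staticmethod
    def _node(value: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(value)
        if _GRAD_ENABLED and any(p.requires_grad or p.parents for p in parents):
            out.parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t.parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate buffers eagerly
                if not node.requires_grad:
                    node.grad = None
            node._backward = None

    # -- pointwise arithmetic ------------------------------------------------

    def __add__(self, other):
        o = _wrap(other)
        return Tensor._node(self.value + o.value, (self, o),
                            lambda g: (self._accum(_unbroadcast(g, self.value.shape)),
                                       o._accum(_unbroadcast(g, o.value.shape))))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.value, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        o = _wrap(other)
        return Tensor._node(self.value * o.value, (self, o),
                            lambda g: (self._accum(_unbroadcast(g * o.value, self.value.shape)),
                                       o._accum(_unbroadcast(g * self.value, o.value.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _wrap(other)
        val = self.value / o.value

        def back(g):
            self._accum(_unbroadcast(g / o.value, self.value.shape))
            o._accum(_unbroadcast(-g * val / o.value, o.value.shape))

        return Tensor._node(val, (self, o), back)

    def sqrt(self):
        val = np.sqrt(self.value)
        return Tensor._node(val, (self,),
                            lambda g: self._accum(g * 0.5 / np.maximum(val, 1e-30)))

    def mean(self):
        n = self.value.size
        return Tensor._node(np.asarray(self.value.mean(), dtype=np.float32), (self,),
                            lambda g: self._accum(np.full_like(self.value, g / n)))

    def sum(self):
        return Tensor._node(np.asarray(self.value.sum(), dtype=np.float32), (self,),
                            lambda g: self._accum(np.full_like(self.value, g)))

    def leaky_relu(self, slope: float = 0.2):
        mask = self.value >= 0
        scale = np.where(mask, np.float32(1.0), np.float32(slope))
        return Tensor._node(self.value * scale, (self,),
                            lambda g: self._accum(g * scale))

    def item(self) -> float:
        return float(self.value)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    g = g.sum(axis=tuple(range(g.ndim - len(shape))))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis (axis 0)."""
    na = a.value.shape[0]
    val = np.concatenate([a.value, b.value], axis=0)
    return Tensor._node(val, (a, b),
                        lambda g: (a._accum(g[:na]), b._accum(g[na:])))


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbor x2 upsampling of a (C, D, H, W) tensor."""
    val = x.value.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def back(g):
        c, d, h, w = x.value.shape
        x._accum(g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)))

    return Tensor._node(val, (x,), back)


def axis_diff(x: Tensor, axis: int) -> Tensor:
    """Forward differences along one axis (output one shorter on that axis)."""
    sl_hi = [slice(None)] * x.value.ndim
    sl_lo = [slice(None)] * x.value.ndim
    sl_hi[axis] = slice(1, None)
    sl_lo[axis] = slice(None, -1)
    sl_hi, sl_lo = tuple(sl_hi), tuple(sl_lo)
    val = x.value[sl_hi] - x.value[sl_lo]

    def back(g):
        gx = np.zeros_like(x.value)
        gx[sl_hi] += g
        gx[sl_lo] -= g
        x._accum(gx)

    return Tensor._node(val, (x,), back)


def boxsum(x: Tensor, window: int) -> Tensor:
    """Sum over a centered window of edge ``window`` (odd), truncated at borders.

    The per-axis operator is symmetric (voxel j contributes to output i
    iff |i-j| <= r), so the adjoint is the same box sum.
    """
    r = window // 2
    val = _boxsum_nd(x.value, r)
    return Tensor._node(val, (x,), lambda g: x._accum(_boxsum_nd(g, r)))


def _boxsum_1d(x: np.ndarray, r: int, axis: int) -> np.ndarray:
    # float64 accumulation: float32 prefix sums lose ~7 digits over long
    # axes, which is catastrophic for the variance cancellation in LNCC
    n = x.shape[axis]
    s = np.cumsum(x, axis=axis, dtype=np.float64)
    pad_shape = list(x.shape)
    pad_shape[axis] = 1
    s = np.concatenate([np.zeros(pad_shape, dtype=np.float32), s], axis=axis)
    hi = np.minimum(np.arange(n) + r, n - 1) + 1
    lo = np.maximum(np.arange(n) - r, 0)
    out = np.take(s, hi, axis=axis) - np.take(s, lo, axis=axis)
    return out.astype(np.float32)


def _boxsum_nd(x: np.ndarray, r: int) -> np.ndarray:
    out = x
    for axis in range(x.ndim - 3, x.ndim):
        out = _boxsum_1d(out, r, axis)
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _offset_slices(k: int, stride: int, out_spatial: tuple[int, int, int]):
    """Strided slices of the padded input feeding each kernel offset."""
    do, ho, wo = out_spatial
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                yield (slice(a, a + stride * (do - 1) + 1, stride),
                       slice(bb, bb + stride * (ho - 1) + 1, stride),
                       slice(c, c + stride * (wo - 1) + 1, stride))


def _conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                    stride: int, pad: int):
    """Shift-and-matmul convolution: one (Cout,Cin)@(Cin,N) product per
    kernel offset — far cheaper on CPU than an im2col gather."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
    out_spatial = tuple((x.shape[i + 1] + 2 * pad - k) // stride + 1 for i in range(3))
    n = out_spatial[0] * out_spatial[1] * out_spatial[2]
    wm = w.reshape(cout, cin, k * k * k)
    out = np.zeros((cout, n), dtype=np.float32)
    for i, sl in enumerate(_offset_slices(k, stride, out_spatial)):
        xs = np.ascontiguousarray(xp[:, sl[0], sl[1], sl[2]]).reshape(cin, n)
        out += wm[:, :, i] @ xs
    out += b[:, None]
    return out.reshape(cout, *out_spatial), xp


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """3D convolution of (Cin, D, H, W) with kernel (Cout, Cin, k, k, k)."""
    val, xp = _conv3d_forward(x.value, w.value, b.value, stride, pad)
    if not _GRAD_ENABLED:
        return Tensor(val)
    cout, cin, k = w.value.shape[0], w.value.shape[1], w.value.shape[2]
    out_spatial = val.shape[1:]
    n = val[0].size

    def back(g):
        gm = g.reshape(cout, n)
        wm = w.value.reshape(cout, cin, k * k * k)
        gw = np.zeros_like(wm)
        gxp = np.zeros_like(xp)
        for i, sl in enumerate(_offset_slices(k, stride, out_spatial)):
            xs = np.ascontiguousarray(xp[:, sl[0], sl[1], sl[2]]).reshape(cin, n)
            gw[:, :, i] = gm @ xs.T
            gxp[:, sl[0], sl[1], sl[2]] += (wm[:, :, i].T @ gm).reshape(
                cin, *out_spatial)
        w._accum(gw.reshape(w.value.shape))
        b._accum(gm.sum(axis=1))
        d, h, wd = x.value.shape[1:]
        x._accum(gxp[:, pad:pad + d, pad:pad + h, pad:pad + wd] if pad else gxp)

    return Tensor._node(val, (x, w, b), back)


# ---------------------------------------------------------------------------
# trilinear resampling at flow-displaced coordinates
# ---------------------------------------------------------------------------

def sample_displaced(const_values: np.ndarray, flow: Tensor) -> Tensor:
    """Sample a constant (C, D, H, W) array at ``x + flow(x)``, clamp-to-edge.

    This is both the spatial-transformer warp (C=1, values = moving image)
    and the flow-aggregator resample (C=3, values = previous aggregate).
    The gradient w.r.t. the flow is the spatial derivative of the
    trilinear interpolant; it is zero wherever the coordinate clamps.
    """
    c = const_values.shape[0]
    spatial = const_values.shape[1:]
    grid = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float32) for n in spatial),
                                indexing="ij"), axis=0)
    coords = grid + flow.value

    idx0, idx1, frac, interior = [], [], [], []
    for ax in range(3):
        cc = coords[ax]
        interior.append((cc >= 0.0) & (cc <= spatial[ax] - 1.0))
        cc = np.clip(cc, 0.0, spatial[ax] - 1.0)
        f0 = np.floor(cc)
        i0 = f0.astype(np.int64)
        idx0.append(i0)
        idx1.append(np.minimum(i0 + 1, spatial[ax] - 1))
        frac.append((cc - f0).astype(np.float32))

    (d0, h0, w0), (d1, h1, w1) = idx0, idx1
    fd, fh, fw = frac
    gd, gh, gw = 1.0 - fd, 1.0 - fh, 1.0 - fw

    corners = []
    out = np.zeros((c, *spatial), dtype=np.float32)
    for di, wd_, sd in ((d0, gd, -1.0), (d1, fd, 1.0)):
        for hi, wh_, sh in ((h0, gh, -1.0), (h1, fh, 1.0)):
            for wi, ww_, sw in ((w0, gw, -1.0), (w1, fw, 1.0)):
                vals = const_values[:, di, hi, wi]
                out += vals * (wd_ * wh_ * ww_)
                corners.append((vals, wd_, wh_, ww_, sd, sh, sw))

    if not _GRAD_ENABLED:
        return Tensor(out)

    def back(g):
        gflow = np.zeros_like(flow.value)
        for vals, wd_, wh_, ww_, sd, sh, sw in corners:
            gv = (g * vals).sum(axis=0)
            gflow[0] += gv * (sd * wh_ * ww_)
            gflow[1] += gv * (wd_ * sh * ww_)
            gflow[2] += gv * (wd_ * wh_ * sw)
        for ax in range(3):
            gflow[ax] *= interior[ax]
        flow._accum(gflow)

    return Tensor._node(out, (flow,), back)
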