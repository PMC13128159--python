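"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation builds a node holding
references to its parent :class:`Tensor` objects and a closure that maps the
output gradient to parent gradients.  ``Tensor.backward`` runs a topological
sweep.  Only the operations needed by the detection stack are provided; all
data is kept in float32 to bound memory and keep BLAS matmuls fast.

Convolution and pooling are implemented as primitives (im2col + matmul with a
hand-written col2im adjoint) rather than compositions, because they dominate
runtime.  A module-level :class:`MacCounter` can be installed to record
multiply-accumulate counts of every convolution actually executed, which is
how model profiling measures FLOPs.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "mac_counting", "cat", "stack"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class MacCounter:
    """Accumulates multiply-accumulate counts of executed convolutions."""

    def __init__(self) -> None:
        self.macs = 0

    def add(self, n: int) -> None:
        self.macs += int(n)


_mac_counter: Optional[MacCounter] = None


@contextlib.contextmanager
def mac_counting(counter: MacCounter):
    global _mac_counter
    prev = _mac_counter
    _mac_counter = counter
    try:
        yield counter
    finally:
        _mac_counter = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to the reflected ops
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numel(self) -> int:
        return int(self.data.size)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], tuple]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(_needs(p) for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = False
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = self._lift(other)
        return Tensor._make(
            self.data + o.data, (self, o),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        o = self._lift(other)
        return Tensor._make(
            self.data - o.data, (self, o),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(-g, o.data.shape)))

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        o = self._lift(other)
        return Tensor._make(
            self.data * o.data, (self, o),
            lambda g: (_unbroadcast(g * o.data, self.data.shape),
                       _unbroadcast(g * self.data, o.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        return Tensor._make(
            self.data / o.data, (self, o),
            lambda g: (_unbroadcast(g / o.data, self.data.shape),
                       _unbroadcast(-g * self.data / (o.data * o.data), o.data.shape)))

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, p: float):
        d = self.data
        return Tensor._make(d ** p, (self,), lambda g: (g * p * d ** (p - 1),))

    def __matmul__(self, other):
        o = self._lift(other)
        y = self.data @ o.data

        def back(g):
            ga = g @ np.swapaxes(o.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.data.shape), _unbroadcast(gb, o.data.shape))

        return Tensor._make(y, (self, o), back)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), back)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        d = self.data

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, d.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, d.shape).copy(),)

        return Tensor._make(d.sum(axis=axis, keepdims=keepdims, dtype=np.float32),
                            (self,), back)

    def mean(self, axis=None, keepdims=False):
        d = self.data
        n = d.size if axis is None else np.prod(
            [d.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])

        def back(g):
            if axis is None:
                return (np.broadcast_to(g / n, d.shape).astype(np.float32),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((np.broadcast_to(g2, d.shape) / n).astype(np.float32),)

        return Tensor._make(d.mean(axis=axis, keepdims=keepdims, dtype=np.float32),
                            (self,), back)

    def max(self, axis, keepdims=False):
        d = self.data
        y = d.max(axis=axis, keepdims=True)
        mask = (d == y)
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def back(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((g2 * mask).astype(np.float32),)

        return Tensor._make(y if keepdims else y.squeeze(axis), (self,), back)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        m = self.data > 0
        return Tensor._make(self.data * m, (self,), lambda g: (g * m,))

    def sigmoid(self):
        y = _sigmoid_stable(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y * (1 - y),))

    def silu(self):
        s = _sigmoid_stable(self.data)
        y = self.data * s

        def back(g):
            return (g * (s * (1 + self.data * (1 - s))),)

        return Tensor._make(y, (self,), back)

    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def arctan(self):
        d = self.data
        return Tensor._make(np.arctan(d), (self,), lambda g: (g / (1 + d * d),))

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor._make(y, (self,), lambda g: (g / (2 * y),))

    def softmax(self, axis=-1):
        d = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(d)
        y = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return ((y * (g - dot)).astype(np.float32),)

        return Tensor._make(y, (self,), back)


def _sigmoid_stable(x: np.ndarray) -> np.ndarray:
    # clip so exp never overflows; exp(-37) is already below float32 eps
    return 1.0 / (1.0 + np.exp(-np.clip(x, -37.0, 37.0)))


def _needs(t: Tensor) -> bool:
    return t.requires_grad or t._backward is not None


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tensors, back)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    def back(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, back)


# ---------------------------------------------------------------------------
# Convolution / pooling primitives
# ---------------------------------------------------------------------------

def _pair(p) -> tuple[int, int]:
    return (p, p) if isinstance(p, int) else (int(p[0]), int(p[1]))


def _pad2d(x: np.ndarray, p) -> np.ndarray:
    ph, pw = _pair(p)
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _patches(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> view (N,C,Ho,Wo,kh,kw)."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad) -> np.ndarray:
    """Adjoint of patch extraction. dcols: (N,C,Ho,Wo,kh,kw)."""
    n, c, h, w = xshape
    ph, pw = _pair(pad)
    hp, wp = h + 2 * ph, w + 2 * pw
    out = np.zeros((n, c, hp, wp), dtype=np.float32)
    ho, wo = dcols.shape[2], dcols.shape[3]
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, :, :, i, j]
    return out[:, :, ph:hp - ph or None, pw:wp - pw or None]


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel assumed rectangular OK."""
    xn, wn = x.data, weight.data
    n, cin, h, w = xn.shape
    cout, cin_g, kh, kw = wn.shape
    if cin_g * groups != cin:
        raise ValueError(f"channel mismatch: {cin} in, weight {wn.shape}, groups {groups}")
    ph, pw = _pair(padding)
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (w + 2 * pw - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("spatial dims smaller than kernel")
    xp = _pad2d(xn, padding)
    if _mac_counter is not None:
        _mac_counter.add(n * cout * ho * wo * cin_g * kh * kw)

    if groups == 1:
        cols = np.ascontiguousarray(
            _patches(xp, kh, kw, stride).transpose(0, 1, 4, 5, 2, 3)
        ).reshape(n, cin * kh * kw, ho * wo)
        wmat = wn.reshape(cout, cin * kh * kw)
        y = (wmat @ cols).reshape(n, cout, ho, wo)

        def back(g):
            gy = g.reshape(n, cout, ho * wo)
            gw = np.tensordot(gy, cols, axes=([0, 2], [0, 2])).reshape(wn.shape)
            dcols = (wmat.T @ gy).reshape(n, cin, kh, kw, ho, wo).transpose(0, 1, 4, 5, 2, 3)
            gx = _col2im(dcols, xn.shape, kh, kw, stride, padding)
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

    elif groups == cin and cout == cin:
        # depthwise, channel multiplier 1
        pat = _patches(xp, kh, kw, stride)  # (N,C,Ho,Wo,kh,kw)
        wd = wn.reshape(cin, kh, kw)
        y = np.einsum("nchwij,cij->nchw", pat, wd, optimize=True).astype(np.float32)

        def back(g):
            gw = np.einsum("nchw,nchwij->cij", g, pat, optimize=True).reshape(wn.shape)
            dcols = g[..., None, None] * wd[None, :, None, None, :, :]
            gx = _col2im(dcols.astype(np.float32), xn.shape, kh, kw, stride, padding)
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

    else:
        # general grouped convolution via per-group matmul
        cpg_in, cpg_out = cin // groups, cout // groups
        cols = np.ascontiguousarray(
            _patches(xp, kh, kw, stride).transpose(0, 1, 4, 5, 2, 3)
        ).reshape(n, groups, cpg_in * kh * kw, ho * wo)
        wmat = wn.reshape(groups, cpg_out, cpg_in * kh * kw)
        y = np.einsum("gok,ngkl->ngol", wmat, cols, optimize=True).reshape(n, cout, ho, wo)
        y = y.astype(np.float32)

        def back(g):
            gy = g.reshape(n, groups, cpg_out, ho * wo)
            gw = np.einsum("ngol,ngkl->gok", gy, cols, optimize=True).reshape(wn.shape)
            dcols = np.einsum("gok,ngol->ngkl", wmat, gy, optimize=True)
            dcols = dcols.reshape(n, cin, kh, kw, ho, wo).transpose(0, 1, 4, 5, 2, 3)
            gx = _col2im(np.ascontiguousarray(dcols, dtype=np.float32),
                         xn.shape, kh, kw, stride, padding)
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

    if bias is not None:
        y = y + bias.data.reshape(1, cout, 1, 1)
        parents: tuple = (x, weight, bias)
    else:
        parents = (x, weight)
    return Tensor._make(y, parents, back)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    xn = x.data
    n, c, h, w = xn.shape
    xp = _pad2d(xn, padding)
    if padding:
        xp[:, :, :padding, :] = -np.inf
        xp[:, :, -padding:, :] = -np.inf
        xp[:, :, :, :padding] = -np.inf
        xp[:, :, :, -padding:] = -np.inf
    pat = _patches(xp, kernel, kernel, stride)
    ho, wo = pat.shape[2], pat.shape[3]
    flat = pat.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def back(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dcols = dflat.reshape(n, c, ho, wo, kernel, kernel)
        return (_col2im(dcols, xn.shape, kernel, kernel, stride, padding),)

    return Tensor._make(y.astype(np.float32), (x,), back)


def upsample_nearest2x(x: Tensor) -> Tensor:
    xn = x.data
    y = xn.repeat(2, axis=2).repeat(2, axis=3)

    def back(g):
        n, c, h2, w2 = g.shape
        return (g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)),)

    return Tensor._make(y, (x,), back)
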