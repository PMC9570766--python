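"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the segmentation network needs: broadcast
arithmetic, matmul, reductions, elementwise nonlinearities, softmax,
2-D convolution (with stride/padding/groups), nearest and bilinear 2x
upsampling, batch normalisation and channel concatenation.  Gradients are
accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "maximum", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- graph ops
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                elif parent._backward is None:
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape),
            )

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            return (g @ other.data.swapaxes(-1, -2), self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(out_data, (self, other), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- elementwise
    def relu(self):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, 0), (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return Tensor._make(s, (self,), bwd)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # --------------------------------------------------------------- spatial
    def global_avg_pool(self):
        """(N, C, H, W) -> (N, C, 1, 1) mean over spatial dims."""
        return self.mean(axis=(2, 3), keepdims=True)

    def upsample_nearest2x(self):
        n, c, h, w = self.data.shape
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def bwd(g):
            return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

        return Tensor._make(out_data, (self,), bwd)

    def upsample_bilinear2x(self):
        n, c, h, w = self.data.shape
        mh = _bilinear2x_matrix(h, self.data.dtype)
        mw = _bilinear2x_matrix(w, self.data.dtype)
        out_data = np.einsum("ij,ncjk,lk->ncil", mh, self.data, mw, optimize=True)

        def bwd(g):
            return (np.einsum("ji,ncjk,kl->ncil", mh, g, mw, optimize=True),)

        return Tensor._make(out_data, (self,), bwd)

    def pad2d(self, ph: int, pw: int):
        if ph == 0 and pw == 0:
            return self
        out_data = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

        def bwd(g):
            return (g[:, :, ph: g.shape[2] - ph, pw: g.shape[3] - pw],)

        return Tensor._make(out_data, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bwd)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; at ties the gradient goes to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bwd(g):
        return (
            _unbroadcast(g * take_a, a.data.shape),
            _unbroadcast(g * ~take_a, b.data.shape),
        )

    return Tensor._make(out_data, (a, b), bwd)


# ------------------------------------------------------------------ helpers

_BL_CACHE: dict = {}


def _bilinear2x_matrix(n: int, dtype) -> np.ndarray:
    """Interpolation matrix (2n x n) for x2 bilinear upsampling.

    Output sample o lies at input coordinate (o + 0.5)/2 - 0.5, clamped at the
    borders (the half-pixel-centre convention).
    """
    key = (n, np.dtype(dtype).str)
    m = _BL_CACHE.get(key)
    if m is None:
        m = np.zeros((2 * n, n), dtype=dtype)
        for o in range(2 * n):
            x = (o + 0.5) / 2.0 - 0.5
            x = min(max(x, 0.0), n - 1.0)
            i0 = int(np.floor(x))
            i1 = min(i0 + 1, n - 1)
            f = x - i0
            m[o, i0] += 1.0 - f
            m[o, i1] += f
        _BL_CACHE[key] = m
    return m


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(N,C,H,W) -> (N,Ho,Wo,C,kh,kw) view-based patch extraction."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw].transpose(0, 2, 3, 1, 4, 5)


def _col2im(cols: np.ndarray, x_shape, kh, kw, sh, sw):
    """Adjoint of `_im2col`: scatter-add patches back onto the padded input."""
    n, c, hp, wp = x_shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    dx = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i: i + sh * ho: sh, j: j + sw * wo: sw] += cols[
                :, :, :, :, i, j
            ].transpose(0, 3, 1, 2)
    return dx


def _conv2d_single(x, w, stride, padding):
    """Un-grouped conv forward returning (out, cols, padded_shape)."""
    sh, sw = stride
    ph, pw = padding
    if ph or pw:
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x
    kh, kw = w.shape[2], w.shape[3]
    cols = _im2col(xp, kh, kw, sh, sw)  # N,Ho,Wo,C,kh,kw
    n, ho, wo = cols.shape[:3]
    cols2 = cols.reshape(n * ho * wo, -1)
    out = cols2 @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, ho, wo, w.shape[0]).transpose(0, 3, 1, 2), cols2, xp.shape


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation. x: (N,Cin,H,W), w: (Cout,Cin/groups,kh,kw)."""
    if isinstance(stride, int):
        stride = (stride, stride)
    if isinstance(padding, int):
        padding = (padding, padding)
    xd, wd = x.data, w.data
    n, cin, _, _ = xd.shape
    cout = wd.shape[0]
    kh, kw = wd.shape[2], wd.shape[3]
    if cin % groups or cout % groups:
        raise ValueError(f"channels ({cin}->{cout}) not divisible by groups={groups}")
    if wd.shape[1] != cin // groups:
        raise ValueError(
            f"weight expects {wd.shape[1] * groups} input channels, got {cin}"
        )

    outs, caches = [], []
    cg, og = cin // groups, cout // groups
    for g in range(groups):
        o, cols2, xpshape = _conv2d_single(
            xd[:, g * cg:(g + 1) * cg], wd[g * og:(g + 1) * og], stride, padding
        )
        outs.append(o)
        caches.append((cols2, xpshape))
    out_data = outs[0] if groups == 1 else np.concatenate(outs, axis=1)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    sh, sw = stride
    ph, pw = padding

    def bwd(g):
        dx = np.zeros_like(xd)
        dw = np.zeros_like(wd)
        for gi in range(groups):
            cols2, xpshape = caches[gi]
            go = g[:, gi * og:(gi + 1) * og]  # N,og,Ho,Wo
            nho = go.shape[0] * go.shape[2] * go.shape[3]
            go2 = go.transpose(0, 2, 3, 1).reshape(nho, og)
            dw[gi * og:(gi + 1) * og] = (go2.T @ cols2).reshape(og, cg, kh, kw)
            dcols = go2 @ wd[gi * og:(gi + 1) * og].reshape(og, -1)
            dxp = _col2im(dcols, xpshape, kh, kw, sh, sw)
            dx[:, gi * cg:(gi + 1) * cg] = dxp[
                :, :, ph: dxp.shape[2] - ph or None, pw: dxp.shape[3] - pw or None
            ]
        if b is not None:
            db = g.sum(axis=(0, 2, 3))
            return dx, dw, db
        return dx, dw

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats."""
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def bwd(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gi = gamma.data.reshape(1, -1, 1, 1) * inv.reshape(1, -1, 1, 1)
        if training:
            m = xd.shape[0] * xd.shape[2] * xd.shape[3]
            gsum = g.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            gxsum = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            dx = gi * (g - gsum / m - xhat * gxsum / m)
        else:
            dx = gi * g
        return dx, dgamma, dbeta

    return Tensor._make(out_data, (x, gamma, beta), bwd)
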