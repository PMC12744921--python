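"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the
segmentation networks in this package need: dense and depthwise 2D
convolution, 3D convolution, batch normalisation, max pooling, nearest
upsampling, reshapes, concatenation, broadcast arithmetic and the
pointwise nonlinearities.  All computation is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

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

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
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

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self):
        return tsum(self)

    def mean(self):
        return mul(tsum(self), 1.0 / self.size)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast to reach ``g.shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(out_data, (a, b), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def clip(a, lo: float, hi: float):
    """Clamp values; gradient passes only through the un-clamped region."""
    a = as_tensor(a)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * mask)

    return _node(np.clip(a.data, lo, hi), (a,), backward)


def tsum(a):
    a = as_tensor(a)

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return _node(a.data.sum(), (a,), backward)


def reshape(a, shape):
    a = as_tensor(a)
    orig = a.shape

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def slice_depth(a, index: int):
    """Select one depth position from an NCDHW tensor -> NCHW."""
    a = as_tensor(a)

    def backward(g):
        da = np.zeros_like(a.data)
        da[:, :, index] = g
        a._accumulate(da)

    return _node(np.ascontiguousarray(a.data[:, :, index]), (a,), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * y * (1.0 - y))

    return _node(y, (a,), backward)


# ---------------------------------------------------------------------------
# convolution helpers (im2col)
# ---------------------------------------------------------------------------

def _cols2d(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Strided sliding windows of a padded NCHW array.

    Returns a view of shape (N, C, Ho, Wo, kh, kw).
    """
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw, :, :]


def conv2d(x, w, b=None, stride=1, padding=0, groups=1):
    """2D cross-correlation.  x: (N,C,H,W), w: (Cout, C/groups, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    sh = sw = int(stride)
    ph = pw = int(padding)
    N, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x.data
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    win = _cols2d(xp, kh, kw, sh, sw)  # (N,C,Ho,Wo,kh,kw)

    if groups == 1:
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
        out = cols @ w.data.reshape(Cout, -1).T
        out = out.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    elif groups == C and Cg == 1 and Cout == C:
        # depthwise
        out = np.einsum("nchwij,cij->nchw", win, w.data[:, 0], optimize=True)
        cols = None
    else:
        raise NotImplementedError("only dense or depthwise convolution")
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    out = np.ascontiguousarray(out, dtype=np.float32)

    def backward(g):
        # dW
        if groups == 1:
            gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
            dw = (gmat.T @ cols).reshape(w.shape)
        else:
            dw = np.einsum("nchw,nchwij->cij", g, win, optimize=True)[:, None]
        w._accumulate(dw.astype(np.float32))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            if groups == 1:
                dcols = (gmat @ w.data.reshape(Cout, -1)).reshape(N, Ho, Wo, C, kh, kw)
                dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N,C,Ho,Wo,kh,kw)
            else:
                dcols = g[..., None, None] * w.data[None, :, 0][:, :, None, None]
                dcols = dcols.reshape(N, C, Ho, Wo, kh, kw)
            dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += dcols[:, :, :, :, i, j]
            dx = dxp[:, :, ph:ph + H, pw:pw + W] if ph or pw else dxp
            x._accumulate(dx)

    return _node(out, (x, w) if b is None else (x, w, b), backward)


def conv3d(x, w, b=None, stride=(1, 1, 1), padding=(0, 0, 0)):
    """3D cross-correlation.  x: (N,C,D,H,W), w: (Cout,C,kd,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    sd, sh, sw = stride
    pd, ph, pw = padding
    N, C, D, H, W = x.shape
    Cout, _, kd, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw))) \
        if (pd or ph or pw) else x.data
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::sd, ::sh, ::sw]  # (N,C,Do,Ho,Wo,kd,kh,kw)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N * Do * Ho * Wo, C * kd * kh * kw)
    out = cols @ w.data.reshape(Cout, -1).T
    out = out.reshape(N, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1, 1)
    out = np.ascontiguousarray(out, dtype=np.float32)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(-1, Cout)
        w._accumulate((gmat.T @ cols).reshape(w.shape).astype(np.float32))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            dcols = (gmat @ w.data.reshape(Cout, -1)).reshape(N, Do, Ho, Wo, C, kd, kh, kw)
            dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            dxp = np.zeros((N, C, D + 2 * pd, H + 2 * ph, W + 2 * pw), dtype=np.float32)
            for a in range(kd):
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, a:a + sd * Do:sd, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += \
                            dcols[:, :, :, :, :, a, i, j]
            sl = (slice(None), slice(None), slice(pd, pd + D),
                  slice(ph, ph + H), slice(pw, pw + W))
            x._accumulate(dxp[sl] if (pd or ph or pw) else dxp)

    return _node(out, (x, w) if b is None else (x, w, b), backward)


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def maxpool2d(x, kernel=3, stride=2, padding=1):
    x = as_tensor(x)
    N, C, H, W = x.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = _cols2d(xp, k, k, s, s)  # (N,C,Ho,Wo,k,k)
    flat = win.reshape(N, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = np.ascontiguousarray(out, dtype=np.float32)

    def backward(g):
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        ii, jj = np.divmod(idx, k)
        n_i, c_i, ho_i, wo_i = np.indices(idx.shape, sparse=False)
        np.add.at(dxp, (n_i, c_i, ho_i * s + ii, wo_i * s + jj), g)
        x._accumulate(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return _node(out, (x,), backward)


def maxpool3d_spatial(x, kernel=3, stride=2, padding=1):
    """(1,k,k) max-pool with stride (1,s,s) on an NCDHW tensor."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    flat = reshape(x, (N, C * D, H, W))
    pooled = maxpool2d(flat, kernel, stride, padding)
    _, _, Ho, Wo = pooled.shape
    return reshape(pooled, (N, C, D, Ho, Wo))


def upsample2d_nearest(x, factor=2):
    x = as_tensor(x)
    f = int(factor)

    def backward(g):
        N, C, Hf, Wf = g.shape
        gr = g.reshape(N, C, Hf // f, f, Wf // f, f).sum(axis=(3, 5))
        x._accumulate(gr)

    out = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)
    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5):
    """Normalise over all axes except channel (axis 1).

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    when ``training`` is true.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0,) + tuple(range(2, x.ndim))
    bshape = (1, -1) + (1,) * (x.ndim - 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(bshape)) * inv.reshape(bshape)
    out = xhat * gamma.data.reshape(bshape) + beta.data.reshape(bshape)

    m = x.size // x.shape[1]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            gG = g * gamma.data.reshape(bshape)
            if training:
                dxhat_sum = gG.sum(axis=axes).reshape(bshape)
                dxhat_dot = (gG * xhat).sum(axis=axes).reshape(bshape)
                dx = (gG - dxhat_sum / m - xhat * dxhat_dot / m) * inv.reshape(bshape)
            else:
                dx = gG * inv.reshape(bshape)
            x._accumulate(dx.astype(np.float32))

    return _node(out.astype(np.float32), (x, gamma, beta), backward)
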