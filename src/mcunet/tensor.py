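"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation network needs:
2-D (dilated) convolution, 2x2 transposed convolution, max pooling with
ceil-mode padding, nearest/bilinear upsampling, batch normalisation,
channel-wise max/mean, concatenation, elementwise arithmetic, ReLU,
sigmoid and a numerically stable binary cross-entropy on logits.

Gradients are hand-derived and verified against central finite
differences in the test suite.  Arrays follow the (batch, channel, row,
col) layout throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "conv2d",
    "conv_transpose2x2",
    "max_pool2d",
    "upsample_nearest",
    "resize_bilinear",
    "batch_norm2d",
    "channel_max",
    "channel_mean",
    "concat",
    "relu",
    "sigmoid",
    "tsum",
    "tmean",
    "bce_with_logits",
]


class Tensor:
    """A NumPy array plus gradient bookkeeping.

    Parameters
    ----------
    data : array-like
        Payload, converted to ``float64``.
    requires_grad : bool
        Whether ``backward`` should accumulate a gradient here.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operator sugar ------------------------------------------------------
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

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))
    out._backward = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))
    out._backward = lambda g: (
        _unbroadcast(g * b.data, a.shape),
        _unbroadcast(g * a.data, b.shape),
    )
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))
    out._backward = lambda g: (
        _unbroadcast(g / b.data, a.shape),
        _unbroadcast(-g * a.data / (b.data**2), b.shape),
    )
    return out


def tsum(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(), parents=(a,))
    out._backward = lambda g: (np.broadcast_to(g, a.shape).copy(),)
    return out


def tmean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.mean(), parents=(a,))
    out._backward = lambda g: (np.broadcast_to(g / a.data.size, a.shape).copy(),)
    return out


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))
    mask = a.data > 0
    out._backward = lambda g: (g * mask,)
    return out


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    # stable logistic
    s = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                 np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: (g * s * (1.0 - s),)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def channel_max(a: Tensor) -> Tensor:
    """Max over the channel axis, keepdims; used by spatial attention."""
    a = as_tensor(a)
    idx = a.data.argmax(axis=1, keepdims=True)
    out = Tensor(np.take_along_axis(a.data, idx, axis=1), parents=(a,))

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, g, axis=1)
        return (ga,)

    out._backward = backward
    return out


def channel_mean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    c = a.shape[1]
    out = Tensor(a.data.mean(axis=1, keepdims=True), parents=(a,))
    out._backward = lambda g: (np.broadcast_to(g / c, a.shape).copy(),)
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _im2col_indices(kh, kw, out_h, out_w, stride, dil):
    i = (dil * np.arange(kh))[:, None] + stride * np.arange(out_h)[None, :]
    j = (dil * np.arange(kw))[:, None] + stride * np.arange(out_w)[None, :]
    return i, j


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding=0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation (the deep-learning "convolution").

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, kh, kw); ``b``: (Cout,).
    ``padding`` is a scalar or (ph, pw) of zero padding; ``dilation`` is
    the atrous rate r (tap spacing), r = 1 being the dense case.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B, Cin, H, W = x.shape
    Cout, Cw, kh, kw = w.shape
    if Cw != Cin:
        raise ValueError(f"channel mismatch: input has {Cin}, filter expects {Cw}")
    ph, pw = _pair(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out_h = (H + 2 * ph - dilation * (kh - 1) - 1) // stride + 1
    out_w = (W + 2 * pw - dilation * (kw - 1) - 1) // stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError("spatial extents too small for this kernel/dilation")
    i, j = _im2col_indices(kh, kw, out_h, out_w, stride, dilation)
    cols = xp[:, :, i[:, None, :, None], j[None, :, None, :]]
    # cols: (B, Cin, kh, kw, out_h, out_w)
    y = np.einsum("bckluv,ockl->bouv", cols, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        gw = np.einsum("bckluv,bouv->ockl", cols, g, optimize=True)
        gcols = np.einsum("bouv,ockl->bckluv", g, w.data, optimize=True)
        gxp = np.zeros_like(xp)
        np.add.at(gxp, (slice(None), slice(None), i[:, None, :, None],
                        j[None, :, None, :]), gcols)
        gx = gxp[:, :, ph:ph + H, pw:pw + W]
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    out._backward = backward
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with 2x2 kernel and stride 2 (exact doubling).

    ``w``: (Cin, Cout, 2, 2).  Because stride equals kernel size the output
    windows do not overlap, so the operation is a reshaped einsum.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B, Cin, H, W = x.shape
    Cw, Cout, kh, kw = w.shape
    if (kh, kw) != (2, 2) or Cw != Cin:
        raise ValueError("conv_transpose2x2 expects a (Cin, Cout, 2, 2) filter")
    y6 = np.einsum("bchw,codu->bohdwu", x.data, w.data, optimize=True)
    y = y6.reshape(B, Cout, 2 * H, 2 * W)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        g6 = g.reshape(B, Cout, H, 2, W, 2)
        gx = np.einsum("bohdwu,codu->bchw", g6, w.data, optimize=True)
        gw = np.einsum("bchw,bohdwu->codu", x.data, g6, optimize=True)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: int, *, ceil_mode: bool = True) -> Tensor:
    """Max pooling with stride equal to ``kernel``.

    With ``ceil_mode`` the input is padded with -inf so partial windows at
    the bottom/right edges still produce an output cell.
    """
    x = as_tensor(x)
    B, C, H, W = x.shape
    k = int(kernel)
    if k > H or k > W:
        raise ValueError(f"pooling kernel {k} exceeds spatial extents {(H, W)}")
    if ceil_mode:
        oh, ow = -(-H // k), -(-W // k)
    else:
        oh, ow = H // k, W // k
    Hp, Wp = oh * k, ow * k
    xp = np.full((B, C, Hp, Wp), -np.inf)
    xp[:, :, :H, :W] = x.data
    win = xp.reshape(B, C, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, oh, ow, k * k)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gxp = gwin.reshape(B, C, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Hp, Wp)
        return (gxp[:, :, :H, :W],)

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int, out_hw: tuple | None = None) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor, optionally cropped.

    Cropping to ``out_hw`` undoes the bottom/right padding that ceil-mode
    pooling introduced, so pool(k) -> upsample(k) round-trips the extents.
    """
    x = as_tensor(x)
    B, C, H, W = x.shape
    f = int(factor)
    full = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)
    if out_hw is None:
        out_hw = (H * f, W * f)
    oh, ow = out_hw
    if oh > H * f or ow > W * f:
        raise ValueError("cannot crop to extents larger than the upsampled map")
    out = Tensor(full[:, :, :oh, :ow], parents=(x,))

    def backward(g):
        gp = np.zeros((B, C, H * f, W * f))
        gp[:, :, :oh, :ow] = g
        return (gp.reshape(B, C, H, f, W, f).sum(axis=(3, 5)),)

    out._backward = backward
    return out


def _linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation weights
    (half-pixel centres, edges clamped)."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    A[np.arange(n_out), lo] += 1 - t
    A[np.arange(n_out), hi] += t
    return A


def resize_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    """Differentiable bilinear resize to ``out_hw`` (separable matmuls)."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    oh, ow = out_hw
    Ah = _linear_resize_matrix(H, oh)
    Aw = _linear_resize_matrix(W, ow)
    y = np.einsum("ph,bchw,qw->bcpq", Ah, x.data, Aw, optimize=True)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: (
        np.einsum("ph,bcpq,qw->bchw", Ah, g, Aw, optimize=True),)
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running: dict, *,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (batch, row, col) per channel.

    ``running`` is a dict with ``mean``/``var`` arrays updated in place
    during training and used verbatim at inference.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    B, C, H, W = x.shape
    gshape = (1, C, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = B * H * W
        running["mean"] *= 1 - momentum
        running["mean"] += momentum * mu
        unbiased = var * m / max(m - 1, 1)
        running["var"] *= 1 - momentum
        running["var"] += momentum * unbiased
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(gshape)) * inv.reshape(gshape)
        out = Tensor(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape),
                     parents=(x, gamma, beta))

        def backward(g):
            dxhat = g * gamma.data.reshape(gshape)
            s1 = dxhat.sum(axis=(0, 2, 3)).reshape(gshape)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3)).reshape(gshape)
            gx = (inv.reshape(gshape) / m) * (m * dxhat - s1 - xhat * s2)
            return (gx,
                    (g * xhat).sum(axis=(0, 2, 3)),
                    g.sum(axis=(0, 2, 3)))

        out._backward = backward
        return out
    inv = 1.0 / np.sqrt(running["var"] + eps)
    xhat = (x.data - running["mean"].reshape(gshape)) * inv.reshape(gshape)
    out = Tensor(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape),
                 parents=(x, gamma, beta))
    out._backward = lambda g: (
        g * (gamma.data * inv).reshape(gshape),
        (g * xhat).sum(axis=(0, 2, 3)),
        g.sum(axis=(0, 2, 3)))
    return out


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (log-sum-exp stabilised)."""
    logits = as_tensor(logits)
    z, y = logits.data, np.asarray(target, dtype=np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    out._backward = lambda g: (g * (s - y) / z.size,)
    return out
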