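"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations a gated UNet needs: broadcasting
arithmetic, sigmoid/swish/relu nonlinearities, same-padding stride-1
convolution, stride-2 transposed convolution, 2x2 max pooling, batch
normalisation, dropout, channel concatenation, and multiplication of the
height/width axes by fixed matrices (used for the wavelet transform).

All tensors are float32 and laid out NHWC: with channels innermost a 3x3
convolution reduces to nine shifted matrix products over contiguous
memory, which is what keeps CPU training practical.  Convolution weights
are stored (kh, kw, c_in, c_out).

The engine is tape-based: every operation records its parents and a
closure mapping the output gradient to parent gradients; ``backward``
walks the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "scale",
    "sigmoid",
    "swish",
    "relu",
    "concat",
    "conv2d",
    "conv_transpose2d_s2",
    "maxpool2x2",
    "batchnorm2d",
    "dropout",
    "replicate_pad1",
    "matmul_h",
    "matmul_w",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "parents", "grad_fn", "name")

    def __init__(self, data, parents=(), grad_fn=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents
        self.grad_fn = grad_fn
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad):
        """Backpropagate ``grad`` (same shape as ``data``) through the tape."""
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
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node.grad_fn is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.grad_fn(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.astype(np.float32, copy=False)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out.grad_fn = lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out.grad_fn = lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape),
    )
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out.grad_fn = lambda g: (g * s,)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clip keeps exp within float32 range; cheaper than branch-free two-sided forms
    z = np.exp(np.clip(x, -60.0, 60.0, out=np.empty_like(x)), out=np.empty_like(x))
    return z / (1.0 + z)


def sigmoid(a: Tensor) -> Tensor:
    s = _sigmoid(a.data)
    out = Tensor(s, (a,))
    out.grad_fn = lambda g: (g * s * (1.0 - s),)
    return out


def swish(a: Tensor) -> Tensor:
    s = _sigmoid(a.data)
    out = Tensor(a.data * s, (a,))
    # d/dx x*sig(x) = sig(x)*(1 + x*(1-sig(x)))
    out.grad_fn = lambda g: (g * (s * (1.0 + a.data * (1.0 - s))),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out.grad_fn = lambda g: (g * mask,)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out.grad_fn = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


# ---------------------------------------------------------------------------
# convolution machinery (NHWC, shift-and-matmul)


def _shift_corr(xp: np.ndarray, w: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Sum of shifted matrix products: valid correlation of padded input.

    xp: (N, Hp, Wp, C); w: (kh, kw, C, O).  Returns (N, out_h, out_w, O).
    """
    kh, kw = w.shape[:2]
    n = xp.shape[0]
    y = np.zeros((n, out_h, out_w, w.shape[3]), dtype=np.float32)
    for di in range(kh):
        for dj in range(kw):
            y += xp[:, di : di + out_h, dj : dj + out_w, :] @ w[di, dj]
    return y


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """Stride-1 convolution (cross-correlation) with 'same' zero padding by default.

    x: (N, H, W, C); w: (kh, kw, C, O).
    """
    kh, kw, c, o = w.data.shape
    if pad is None:
        pad = kh // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    out_h = xp.shape[1] - kh + 1
    out_w = xp.shape[2] - kw + 1
    y = _shift_corr(xp, w.data, out_h, out_w)
    if b is not None:
        y += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents)

    def grad_fn(g):
        # grad wrt x: full correlation with spatially flipped, channel-swapped kernel
        fp = kh - 1 - pad
        gp = np.pad(g, ((0, 0), (fp, fp), (fp, fp), (0, 0))) if fp else g
        w_flip = w.data[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh, kw, O, C)
        gx = _shift_corr(gp, w_flip, x.data.shape[1], x.data.shape[2])
        # grad wrt w: per-shift contraction over batch and space
        gw = np.empty_like(w.data)
        for di in range(kh):
            for dj in range(kw):
                gw[di, dj] = np.tensordot(
                    xp[:, di : di + out_h, dj : dj + out_w, :], g, axes=([0, 1, 2], [0, 1, 2])
                )
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 1, 2))

    out.grad_fn = grad_fn
    return out


def conv_transpose2d_s2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3 transposed convolution with stride 2 doubling the spatial size.

    Matches the usual framework parameterisation with padding=1 and
    output_padding=1: out[n, 2i+di-1, 2j+dj-1, o] += x[n, i, j, c] * w[di, dj, c, o].
    """
    n, h, wd, c = x.data.shape
    kh, kw, cin, cout = w.data.shape
    assert cin == c and kh == 3 and kw == 3
    tmp = np.zeros((n, 2 * h + 2, 2 * wd + 2, cout), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            tmp[:, di : di + 2 * h : 2, dj : dj + 2 * wd : 2, :] += x.data @ w.data[di, dj]
    y = tmp[:, 1 : 2 * h + 1, 1 : 2 * wd + 1, :]
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents)

    def grad_fn(g):
        gp = np.zeros((n, 2 * h + 2, 2 * wd + 2, cout), dtype=np.float32)
        gp[:, 1 : 2 * h + 1, 1 : 2 * wd + 1, :] = g
        gx = np.zeros_like(x.data)
        gw = np.empty_like(w.data)
        for di in range(3):
            for dj in range(3):
                sl = gp[:, di : di + 2 * h : 2, dj : dj + 2 * wd : 2, :]
                gx += sl @ w.data[di, dj].T
                gw[di, dj] = np.tensordot(x.data, sl, axes=([0, 1, 2], [0, 1, 2]))
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 1, 2))

    out.grad_fn = grad_fn
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial dims"
    r = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    r = np.ascontiguousarray(r).reshape(n, h // 2, w // 2, c, 4)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, (x,))

    def grad_fn(g):
        gr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return (np.ascontiguousarray(gx),)

    out.grad_fn = grad_fn
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place when training."""
    if training:
        mean = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean) * inv
    out = Tensor(gamma.data * xhat + beta.data, (x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def grad_fn(g):
        ggamma = (g * xhat).sum(axis=(0, 1, 2))
        gbeta = g.sum(axis=(0, 1, 2))
        gxhat = g * gamma.data
        if training:
            s1 = gxhat.sum(axis=(0, 1, 2))
            s2 = (gxhat * xhat).sum(axis=(0, 1, 2))
            gx = (inv / m) * (m * gxhat - s1 - xhat * s2)
        else:
            gx = gxhat * inv
        return gx.astype(np.float32, copy=False), ggamma, gbeta

    out.grad_fn = grad_fn
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out = Tensor(x.data * mask, (x,))
    out.grad_fn = lambda g: (g * mask,)
    return out


def replicate_pad1(a: Tensor) -> Tensor:
    """Pad H and W by one pixel replicating the border (for edge-safe filtering)."""
    out = Tensor(np.pad(a.data, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge"), (a,))

    def grad_fn(g):
        gx = g[:, 1:-1, 1:-1, :].copy()
        gx[:, 0, :, :] += g[:, 0, 1:-1, :]
        gx[:, -1, :, :] += g[:, -1, 1:-1, :]
        gx[:, :, 0, :] += g[:, 1:-1, 0, :]
        gx[:, :, -1, :] += g[:, 1:-1, -1, :]
        gx[:, 0, 0, :] += g[:, 0, 0, :]
        gx[:, 0, -1, :] += g[:, 0, -1, :]
        gx[:, -1, 0, :] += g[:, -1, 0, :]
        gx[:, -1, -1, :] += g[:, -1, -1, :]
        return (gx,)

    out.grad_fn = grad_fn
    return out


def matmul_h(x: Tensor, m: np.ndarray) -> Tensor:
    """Apply fixed matrix ``m`` to the height axis of an NHWC tensor."""
    y = np.einsum("ij,njwc->niwc", m, x.data, optimize=True).astype(np.float32)
    out = Tensor(y, (x,))
    out.grad_fn = lambda g: (
        np.einsum("ij,niwc->njwc", m, g, optimize=True).astype(np.float32),
    )
    return out


def matmul_w(x: Tensor, m: np.ndarray) -> Tensor:
    """Apply fixed matrix ``m`` to the width axis of an NHWC tensor."""
    y = np.einsum("ij,nhjc->nhic", m, x.data, optimize=True).astype(np.float32)
    out = Tensor(y, (x,))
    out.grad_fn = lambda g: (
        np.einsum("ij,nhic->nhjc", m, g, optimize=True).astype(np.float32),
    )
    return out
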