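"""Neural-network primitives (conv, pooling, sampling, losses) on the tape."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "conv1d_channels",
    "maxpool2d",
    "global_avg_pool",
    "upsample_nearest2",
    "bilinear_sample",
    "softmax_cross_entropy",
    "bce_with_logits",
    "smooth_l1",
    "softmax",
]


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0) -> Tensor:
    """2-D cross-correlation, NCHW layout, im2col + matmul.

    ``w``: (F, C, kh, kw); ``padding`` may be an int or (ph, pw).
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    wmat = w.data.reshape(F, -1)
    out_data = cols @ wmat.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bwd(g):
        go = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, F)
        w._accum((go.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accum(go.sum(axis=0))
        gcols = (go @ wmat).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += gcols[
                    :, :, :, :, i, j
                ]
        gx = gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp
        x._accum(gx)

    out._backward = bwd
    return out


def conv1d_channels(x: Tensor, w: Tensor, k: int) -> Tensor:
    """1-D convolution across the channel axis of a pooled (N, C) tensor.

    Used by ECA: the channel descriptor is treated as a length-C signal and
    convolved with a shared kernel of odd size ``k`` (same padding).
    """
    N, C = x.data.shape
    x4 = x.reshape(N, 1, 1, C)
    w4 = w.reshape(1, 1, 1, k)
    out = conv2d(x4, w4, None, stride=1, padding=(0, k // 2))
    return out.reshape(N, C)


def maxpool2d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Max pooling; ``kernel == 1`` with stride 2 degenerates to subsampling."""
    stride = kernel if stride is None else stride
    if kernel == 1:
        return x[:, :, ::stride, ::stride]
    if kernel != stride:
        raise NotImplementedError("only kernel == stride pooling is supported")
    N, C, H, W = x.data.shape
    Ho, Wo = H // kernel, W // kernel
    xc = x[:, :, : Ho * kernel, : Wo * kernel] if (H % kernel or W % kernel) else x
    v = xc.reshape(N, C, Ho, kernel, Wo, kernel)
    v = v.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, kernel * kernel)
    return v.max(axis=4)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def upsample_nearest2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _prev=(x,))

    def bwd(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def bilinear_sample(feat: Tensor, batch_idx: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> Tensor:
    """Differentiable bilinear sampling of NCHW features at continuous points.

    ``ys``/``xs`` are arrays of shape S (any shape) of continuous pixel-center
    coordinates; ``batch_idx`` broadcasts against them.  Returns a tensor of
    shape S + (C,).  Gradients flow to ``feat`` only (sampling positions are
    treated as constants, the usual ROI-align approximation).
    """
    N, C, H, W = feat.data.shape
    ys = np.asarray(ys, dtype=np.float64)
    xs = np.asarray(xs, dtype=np.float64)
    batch_idx = np.broadcast_to(np.asarray(batch_idx), ys.shape)
    y0 = np.clip(np.floor(ys).astype(np.int64), 0, H - 1)
    x0 = np.clip(np.floor(xs).astype(np.int64), 0, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy1 = np.clip(ys - y0, 0.0, 1.0)
    wx1 = np.clip(xs - x0, 0.0, 1.0)
    wy0, wx0 = 1.0 - wy1, 1.0 - wx1
    corners = [
        (y0, x0, (wy0 * wx0).astype(np.float32)),
        (y0, x1, (wy0 * wx1).astype(np.float32)),
        (y1, x0, (wy1 * wx0).astype(np.float32)),
        (y1, x1, (wy1 * wx1).astype(np.float32)),
    ]
    data = np.zeros(ys.shape + (C,), dtype=np.float32)
    fd = feat.data
    for yy, xx, wgt in corners:
        data += fd[batch_idx, :, yy, xx] * wgt[..., None]
    out = Tensor(data, _prev=(feat,))

    def bwd(g):
        gf = np.zeros_like(fd)
        for yy, xx, wgt in corners:
            np.add.at(gf, (batch_idx, slice(None), yy, xx), g * wgt[..., None])
        feat._accum(gf)

    out._backward = bwd
    return out


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    m = logits.data.max(axis=axis, keepdims=True)
    shifted = logits - Tensor(m)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    N = logits.data.shape[0]
    z = logits.data.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(N), labels].mean()
    out = Tensor(np.float32(loss), _prev=(logits,))
    p = np.exp(logp)

    def bwd(g):
        gz = p.copy()
        gz[np.arange(N), labels] -= 1.0
        logits._accum((g * gz / N).astype(np.float32))

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all elements, numerically stable."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data.astype(np.float64)
    # log(1+exp(-|z|)) + max(z,0) - z*t
    loss = (np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * t).mean()
    out = Tensor(np.float32(loss), _prev=(logits,))
    n = z.size
    sig = 1.0 / (1.0 + np.exp(-z))

    def bwd(g):
        logits._accum((g * (sig - t) / n).astype(np.float32))

    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0 / 9.0, divisor: float | None = None) -> Tensor:
    """Huber/smooth-L1 loss summed over elements and divided by ``divisor``.

    ``divisor`` defaults to the number of elements (i.e. a mean).
    """
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    ad = np.abs(d)
    elem = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    div = float(d.size) if divisor is None else float(divisor)
    out = Tensor(np.float32(elem.sum() / div), _prev=(pred,))

    def bwd(g):
        gd = np.where(ad < beta, d / beta, np.sign(d))
        pred._accum((g * gd / div).astype(np.float32))

    out._backward = bwd
    return out
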