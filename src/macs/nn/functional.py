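"""Differentiable operations: convolution, activations, resampling, losses."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor

_EPS = 1e-7  # probability clipping for numerically safe logs


# ----------------------------------------------------------------------
# convolution (im2col with a kernel-position loop; BLAS does the work)

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw, ho, wo) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += dcols[:, :, i, j]
    if ph or pw:
        return dxp[:, :, ph:ph + h, pw:pw + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin != cin_g * groups:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_g * groups}")
    outs, caches = [], []
    for g in range(groups):
        xs = x.data[:, g * cin_g:(g + 1) * cin_g]
        ws = weight.data[g * (cout // groups):(g + 1) * (cout // groups)]
        cols, ho, wo = _im2col(xs, kh, kw, stride, stride, padding, padding)
        o = np.matmul(ws.reshape(ws.shape[0], -1), cols)  # (n, cout/g, ho*wo)
        outs.append(o.reshape(n, -1, ho, wo))
        caches.append(cols)
    out_data = outs[0] if groups == 1 else np.concatenate(outs, axis=1)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    out = Tensor(out_data, True, (x, weight) + ((bias,) if bias is not None else ()))
    ho, wo = out_data.shape[2], out_data.shape[3]

    def _bwd(grad):
        dw = np.empty_like(weight.data)
        dx = np.empty_like(x.data)
        cg = cout // groups
        for g in range(groups):
            gg = grad[:, g * cg:(g + 1) * cg].reshape(n, cg, -1)
            cols = caches[g]
            dw[g * cg:(g + 1) * cg] = np.matmul(gg, cols.transpose(0, 2, 1)).sum(0).reshape(cg, cin_g, kh, kw)
            ws = weight.data[g * cg:(g + 1) * cg].reshape(cg, -1)
            dcols = np.matmul(ws.T, gg)
            dx[:, g * cin_g:(g + 1) * cin_g] = _col2im(
                dcols, (n, cin_g, h, w), kh, kw, stride, stride, padding, padding, ho, wo)
        x.accumulate_grad(dx)
        weight.accumulate_grad(dw)
        if bias is not None:
            bias.accumulate_grad(grad.sum(axis=(0, 2, 3)))

    out._backward = _bwd
    return out


# ----------------------------------------------------------------------
# activations

def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30.0, 30.0)))
    out = Tensor(y, True, (x,))

    def _bwd(g):
        x.accumulate_grad(g * y * (1.0 - y))

    out._backward = _bwd
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), True, (x,))

    def _bwd(g):
        x.accumulate_grad(np.where(mask, g, slope * g))

    out._backward = _bwd
    return out


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


# ----------------------------------------------------------------------
# shape ops

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, start + s)
            t.accumulate_grad(g[tuple(idx)])
            start += s

    out._backward = _bwd
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Integer-factor nearest-neighbour upsampling of an NCHW tensor."""
    if factor == 1:
        return x
    out = Tensor(x.data.repeat(factor, axis=2).repeat(factor, axis=3), True, (x,))
    n, c, h, w = x.shape

    def _bwd(g):
        x.accumulate_grad(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    out._backward = _bwd
    return out


def mean_tensors(tensors: list[Tensor]) -> Tensor:
    """Elementwise arithmetic mean of equally-shaped tensors."""
    acc = tensors[0]
    for t in tensors[1:]:
        acc = acc + t
    return acc * Tensor(np.asarray(1.0 / len(tensors), dtype=DTYPE))


# ----------------------------------------------------------------------
# losses (mean reductions accumulate in float64)

def bce(pred: Tensor, target) -> Tensor:
    """Binary cross-entropy, natural log, mean over all elements.

    `target` may be an array or a scalar (constant domain label).
    Probabilities are clipped to [1e-7, 1 - 1e-7]; gradients vanish in
    the clipped region, mirroring the saturated-sigmoid regime.
    """
    t = np.broadcast_to(np.asarray(target, dtype=DTYPE), pred.shape)
    inside = (pred.data > _EPS) & (pred.data < 1.0 - _EPS)
    p = np.clip(pred.data, _EPS, 1.0 - _EPS).astype(np.float64)
    val = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()
    out = Tensor(val, True, (pred,))
    n = pred.data.size

    def _bwd(g):
        dp = np.where(inside, (-t / p + (1.0 - t) / (1.0 - p)) / n, 0.0)
        pred.accumulate_grad(g * dp)

    out._backward = _bwd
    return out


def mse(pred: Tensor, target) -> Tensor:
    t = np.asarray(target, dtype=DTYPE)
    diff = pred.data.astype(np.float64) - t
    out = Tensor(np.mean(diff * diff), True, (pred,))
    n = pred.data.size

    def _bwd(g):
        pred.accumulate_grad(g * 2.0 * diff / n)

    out._backward = _bwd
    return out
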