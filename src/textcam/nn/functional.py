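"""Differentiable array operations used by the network layers."""

from __future__ import annotations

from typing import Optional

import numpy as np

from textcam.nn.autograd import Tensor, _make


def _gather_windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
                    ho: int, wo: int) -> np.ndarray:
    """Stack sliding windows: padded (N,C,Hp,Wp) -> (N,C,kh,kw,ho,wo)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * (ho - 1) + 1 : sh,
                                  j : j + sw * (wo - 1) + 1 : sw]
    return cols


def _scatter_windows(dcols: np.ndarray, xp_shape: tuple, kh: int, kw: int,
                     sh: int, sw: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_gather_windows` (overlap-add)."""
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * (ho - 1) + 1 : sh,
                j : j + sw * (wo - 1) + 1 : sw] += dcols[:, :, i, j]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    f, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {c2}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: output would be {ho}x{wo} for input {h}x{w}")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _gather_windows(xp, kh, kw, stride, stride, ho, wo)
    k_dim, p_dim = c * kh * kw, ho * wo
    # one large GEMM: (f, K) @ (K, n*P)
    cols_k = np.ascontiguousarray(
        cols.reshape(n, k_dim, p_dim).transpose(1, 0, 2)
    ).reshape(k_dim, n * p_dim)
    w2 = wd.reshape(f, k_dim)
    out = (w2 @ cols_k).reshape(f, n, ho, wo).transpose(1, 0, 2, 3).copy()
    if bias is not None:
        out += bias.data.reshape(1, f, 1, 1)

    def backward(g: np.ndarray) -> None:
        gk = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(f, n * p_dim)
        if weight.needs_grad:
            weight.accumulate((gk @ cols_k.T).reshape(wd.shape))
        if bias is not None and bias.needs_grad:
            bias.accumulate(g.sum(axis=(0, 2, 3)))
        if x.needs_grad:
            dcols_k = w2.T @ gk
            dcols = (
                dcols_k.reshape(k_dim, n, p_dim)
                .transpose(1, 0, 2)
                .reshape(n, c, kh, kw, ho, wo)
            )
            dxp = _scatter_windows(dcols, xp.shape, kh, kw, stride, stride, ho, wo)
            x.accumulate(dxp[:, :, padding : padding + h, padding : padding + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    xd = x.data
    n, c, h, w = xd.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    cols = _gather_windows(xp, kernel, kernel, stride, stride, ho, wo)
    flat = cols.reshape(n, c, kernel * kernel, ho, wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g: np.ndarray) -> None:
        if not x.needs_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[:, :, None], g[:, :, None], axis=2)
        dcols = dflat.reshape(n, c, kernel, kernel, ho, wo)
        dxp = _scatter_windows(dcols, xp.shape, kernel, kernel, stride, stride, ho, wo)
        x.accumulate(dxp[:, :, padding : padding + h, padding : padding + w])

    return _make(out, (x,), backward)


def max_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    xd = x.data
    n, c, ln = xd.shape
    lo = (ln - kernel) // stride + 1
    cols = np.empty((n, c, kernel, lo), dtype=xd.dtype)
    for i in range(kernel):
        cols[:, :, i] = xd[:, :, i : i + stride * (lo - 1) + 1 : stride]
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g: np.ndarray) -> None:
        if not x.needs_grad:
            return
        dcols = np.zeros_like(cols)
        np.put_along_axis(dcols, arg[:, :, None], g[:, :, None], axis=2)
        dx = np.zeros_like(xd)
        for i in range(kernel):
            dx[:, :, i : i + stride * (lo - 1) + 1 : stride] += dcols[:, :, i]
        x.accumulate(dx)

    return _make(out, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 momentum: float = 0.1, eps: float = 1e-5,
                 training: bool = True) -> Tensor:
    xd = x.data
    n, c, h, w = xd.shape
    m = n * h * w
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        # running stats use the unbiased variance, batch normalization the biased one
        unbiased = var * (m / max(1, m - 1))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean = running_mean.astype(np.float32)
        var = running_var.astype(np.float32)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g: np.ndarray) -> None:
        if gamma.needs_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.needs_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if not x.needs_grad:
            return
        dxhat = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (invstd.reshape(1, c, 1, 1) / m) * (m * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * invstd.reshape(1, c, 1, 1)
        x.accumulate(dx.astype(np.float32))

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        if x.needs_grad:
            x.accumulate(g * mask)

    return _make(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add: shape mismatch {a.data.shape} vs {b.data.shape}")
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.needs_grad:
            a.accumulate(g)
        if b.needs_grad:
            b.accumulate(g)

    return _make(out, (a, b), backward)


def linear(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    out = x.data @ weight.data.T
    if bias is not None:
        out += bias.data

    def backward(g: np.ndarray) -> None:
        if weight.needs_grad:
            weight.accumulate(g.T @ x.data)
        if bias is not None and bias.needs_grad:
            bias.accumulate(g.sum(axis=0))
        if x.needs_grad:
            x.accumulate(g @ weight.data)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def global_avg_pool2d(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g: np.ndarray) -> None:
        if x.needs_grad:
            x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _make(out, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    out = x.data.reshape(n, -1)

    def backward(g: np.ndarray) -> None:
        if x.needs_grad:
            x.accumulate(g.reshape(x.data.shape))

    return _make(out, (x,), backward)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of logits (N, C)."""
    n = logits.data.shape[0]
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data, axis=1)
    eps = np.finfo(np.float32).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(g: np.ndarray) -> None:
        if not logits.needs_grad:
            return
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits.accumulate(float(g) * d / n)

    return _make(np.float32(loss), (logits,), backward)
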