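"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape of fused array primitives — exactly the set a 2D encoder–
decoder segmenter needs (stride-1 convolution via im2col, 2x2 max-pooling,
nearest-neighbour upsampling, channel concatenation, batch norm, pointwise
nonlinearities and the two segmentation losses). Gradients of every
primitive are exercised against central finite differences in the test
suite.

Array layout is NCHW throughout. Only scalar-valued tensors may start a
backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "sigmoid",
    "maxpool2x2",
    "upsample2x",
    "concat_channels",
    "add",
    "scale",
    "batchnorm2d",
    "bce_with_logits_loss",
    "soft_dice_loss",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep U-Net graphs overflow recursion
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g


def _out(data, parents, backward) -> Tensor:
    t = Tensor(data, parents=parents)
    if t.requires_grad:
        t._backward = backward
    return t


# ---------------------------------------------------------------------------
# pointwise and structural primitives

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return _out(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-branch logistic
    z = x.data
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))

    def backward(g):
        x._accum(g * p * (1.0 - p))

    return _out(p, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add requires equal shapes, got {a.shape} vs {b.shape}")

    def backward(g):
        a._accum(g)
        b._accum(g)

    return _out(a.data + b.data, (a, b), backward)


def scale(x: Tensor, c: float) -> Tensor:
    def backward(g):
        x._accum(g * c)

    return _out(x.data * c, (x,), backward)


def concat_channels(parts: list[Tensor]) -> Tensor:
    sizes = [p.shape[1] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for p, gp in zip(parts, np.split(g, splits, axis=1)):
            p._accum(gp)

    return _out(np.concatenate([p.data for p in parts], axis=1), tuple(parts), backward)


# ---------------------------------------------------------------------------
# convolution (stride 1, symmetric zero padding)

def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """2D cross-correlation, NCHW, stride 1.

    ``w`` has shape (C_out, C_in, kh, kw); output spatial size equals input
    when ``padding = (k - 1) / 2``.
    """
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = h + 2 * padding - kh + 1
    wo = wd + 2 * padding - kw + 1
    # (n, cin, ho, wo, kh, kw) view, flattened for one large matmul
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = (cols @ wmat.T + b.data).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, cin, kh, kw)
            dcols = dcols.transpose(4, 5, 0, 3, 1, 2)  # (kh, kw, n, cin, ho, wo)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u:u + ho, v:v + wo] += dcols[u, v]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return _out(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# resolution changes

def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    xr = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, ho, wo, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, h, w))

    return _out(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _out(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalisation

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
    """Per-channel batch normalisation; updates running stats in place."""
    n, c, h, w = x.shape
    gm = gamma.data.reshape(1, c, 1, 1)
    bt = beta.data.reshape(1, c, 1, 1)
    if training:
        m = n * h * w
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running_mean *= 1 - momentum
        running_mean += momentum * mu.ravel()
        running_var *= 1 - momentum
        running_var += momentum * var.ravel() * (m / max(m - 1, 1))
        ivstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * ivstd

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gm
                dvar = (dxhat * (x.data - mu)).sum(axis=(0, 2, 3), keepdims=True) * (
                    -0.5
                ) * ivstd**3
                dmu = -dxhat.sum(axis=(0, 2, 3), keepdims=True) * ivstd + dvar * (
                    -2.0 / m
                ) * (x.data - mu).sum(axis=(0, 2, 3), keepdims=True)
                x._accum(dxhat * ivstd + dvar * 2.0 * (x.data - mu) / m + dmu / m)

    else:
        ivstd = 1.0 / np.sqrt(running_var.reshape(1, c, 1, 1) + eps)
        xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * ivstd

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(g * gm * ivstd)

    return _out(gm * xhat + bt, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses (logit-space, numerically stable)

def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits: max(z,0) - z t + log(1 + e^-|z|)."""
    z = logits.data
    t = np.asarray(target, dtype=np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    inv = 1.0 / z.size

    def backward(g):
        logits._accum(g * (p - t) * inv)

    return _out(loss.mean(), (logits,), backward)


def soft_dice_loss(logits: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice between sigmoid(logits) and a binary target."""
    z = logits.data
    t = np.asarray(target, dtype=np.float64)
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    s_pt = float((p * t).sum())
    s_p = float(p.sum())
    s_t = float(t.sum())
    denom = s_p + s_t + eps
    dice = (2.0 * s_pt + eps) / denom

    def backward(g):
        # d(1 - dice)/dp_i, then chain through the logistic
        dL_dp = -(2.0 * t * denom - (2.0 * s_pt + eps)) / denom**2
        logits._accum(g * dL_dp * p * (1.0 - p))

    return _out(np.float64(1.0 - dice), (logits,), backward)
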