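"""Minimal 3D neural-network layers on numpy with manual backprop.

Sized for the small stride-1 "same"-padding convolutional models this
package trains on CPU: 3D convolution via im2col + matmul, batch
normalization, ReLU, linear layers, global-average / gated pooling, a
fused softmax cross-entropy, and Adam.  Tensors are ``(N, C, D, H, W)``
float64 arrays; every layer exposes ``forward(x, train)`` and
``backward(grad)`` and gradients are verified against finite differences
in the test suite.

Only stride 1 with odd kernels is supported — the network designs used
here deliberately contain no spatial downsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "BatchNorm1d",
    "ReLU",
    "Linear",
    "Sequential",
    "softmax",
    "SoftmaxCrossEntropy",
    "global_average_pool",
    "gated_pool_forward",
    "gated_pool_backward",
    "Adam",
    "save_params",
    "load_params",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("v", "g", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)
        self.name = name

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D+2p, H+2p, W+2p) padded input -> (N*D*H*W, C*k^3) patches."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, D, H, W, k, k, k) -> (N, D, H, W, C, k, k, k)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    n, d, h, w = win.shape[:4]
    return win.reshape(n * d * h * w, -1), (n, d, h, w)


def _conv_same(x: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Stride-1 same-padding correlation; returns (y, cols, spatial)."""
    k = W.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    cols, (n, d, h, w) = _im2col(xp, k)
    Wm = W.reshape(W.shape[0], -1)  # (out, in*k^3)
    y = cols @ Wm.T  # (N*DHW, out)
    y = y.reshape(n, d, h, w, W.shape[0]).transpose(0, 4, 1, 2, 3)
    return y, cols, (n, d, h, w)


class Conv3d:
    """3D convolution, stride 1, odd kernel, same padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd (same padding)")
        fan_in = in_ch * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.W = Param(rng.standard_normal((out_ch, in_ch, kernel, kernel, kernel)) * scale,
                       f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self.kernel = kernel

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y, cols, spatial = _conv_same(x, self.W.v)
        if train:
            self._cols, self._spatial = cols, spatial
        return y + self.b.v[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d, h, w = self._spatial
        out_ch = grad.shape[1]
        gmat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, out_ch)  # (N*DHW, out)
        self.W.g += (gmat.T @ self._cols).reshape(self.W.v.shape)
        self.b.g += grad.sum(axis=(0, 2, 3, 4))
        # dx = conv of grad with spatially flipped, channel-transposed kernels
        Wflip = self.W.v[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dx, _, _ = _conv_same(grad, np.ascontiguousarray(Wflip))
        self._cols = None
        return dx


class BatchNorm3d:
    """Per-channel batch normalization over (N, D, H, W) with running stats."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(n_ch), f"{name}.gamma")
        self.beta = Param(np.zeros(n_ch), f"{name}.beta")
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        if train:
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        return self.gamma.v[None, :, None, None, None] * xhat + self.beta.v[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.g += (grad * xhat).sum(axis=axes)
        self.beta.g += grad.sum(axis=axes)
        g = grad * self.gamma.v[None, :, None, None, None]
        gsum = g.sum(axis=axes)
        gx = (g * xhat).sum(axis=axes)
        dx = (inv[None, :, None, None, None] / m) * (
            m * g
            - gsum[None, :, None, None, None]
            - xhat * gx[None, :, None, None, None]
        )
        self._xhat = None
        return dx


class BatchNorm1d:
    """Feature-wise batch normalization for (N, F) inputs.

    Used on pooled feature vectors: pooling over a small gated region
    leaves features orders of magnitude below unit scale, which stalls
    the classifier head early in training; normalizing restores O(1)
    activations without changing what the features encode.
    """

    def __init__(self, n_feat: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn1d"):
        self.gamma = Param(np.ones(n_feat), f"{name}.gamma")
        self.beta = Param(np.zeros(n_feat), f"{name}.beta")
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0]
        return self.gamma.v * xhat + self.beta.v

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.g += (grad * xhat).sum(axis=0)
        self.beta.g += grad.sum(axis=0)
        g = grad * self.gamma.v
        dx = (inv / m) * (m * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))
        self._xhat = None
        return dx


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "fc"):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.standard_normal((n_in, n_out)) * scale, f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.g += self._x.T @ grad
        self.b.g += grad.sum(axis=0)
        dx = grad @ self.W.v.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SoftmaxCrossEntropy:
    """Mean softmax cross-entropy over the batch; targets are int labels."""

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> float:
        p = softmax(logits)
        self._p, self._t = p, targets
        n = logits.shape[0]
        return float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())

    def backward(self) -> np.ndarray:
        n = self._p.shape[0]
        g = self._p.copy()
        g[np.arange(n), self._t] -= 1.0
        return g / n


def global_average_pool(fmaps: np.ndarray) -> np.ndarray:
    """(N, C, D, H, W) -> (N, C) spatial mean."""
    return fmaps.mean(axis=(2, 3, 4))


def gated_pool_forward(fmaps: np.ndarray, gate: np.ndarray, mode: str) -> np.ndarray:
    """Pool feature maps through a spatial gate.

    ``mode='weighted-average'``: sum(gate*f)/sum(gate) per channel (the
    in-region average when the gate is a binary mask).
    ``mode='global-mean'``: mean over all ROI voxels of gate*f.

    ``gate`` is (N, D, H, W) (or broadcastable) in [0, 1].
    """
    g = gate[:, None] if gate.ndim == 4 else gate
    if mode == "weighted-average":
        denom = g.sum(axis=(2, 3, 4))
        if np.any(denom <= 0):
            raise ValueError("weighted-average gated pooling needs sum(gate) > 0")
        return (fmaps * g).sum(axis=(2, 3, 4)) / denom
    if mode == "global-mean":
        return (fmaps * g).mean(axis=(2, 3, 4))
    raise ValueError(f"unknown pooling mode {mode!r}")


def gated_pool_backward(
    grad: np.ndarray, fmaps: np.ndarray, gate: np.ndarray, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients (d_fmaps, d_gate) of :func:`gated_pool_forward`."""
    g = gate[:, None] if gate.ndim == 4 else gate
    n, c, d, h, w = fmaps.shape
    gexp = grad[:, :, None, None, None]
    if mode == "weighted-average":
        denom = g.sum(axis=(2, 3, 4))[:, :, None, None, None]
        dfm = gexp * g / denom
        pooled = (fmaps * g).sum(axis=(2, 3, 4), keepdims=True) / denom
        dgate = (gexp * (fmaps - pooled) / denom).sum(axis=1)
    elif mode == "global-mean":
        m = d * h * w
        dfm = gexp * g / m
        dgate = (gexp * fmaps / m).sum(axis=1)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return dfm, dgate


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, s in zip(self.params, self.m, self.s):
            if self.weight_decay and p.v.ndim > 1:  # decay weights, not biases/affines
                p.g += self.weight_decay * p.v
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            s[...] = self.b2 * s + (1 - self.b2) * p.g**2
            mhat = m / (1 - self.b1**self.t)
            shat = s / (1 - self.b2**self.t)
            p.v -= self.lr * mhat / (np.sqrt(shat) + self.eps)


def save_params(path, params: list[Param], config: dict | None = None,
                extras: dict[str, np.ndarray] | None = None) -> None:
    """Serialize named parameters (npz) plus a JSON config side file."""
    path = Path(path)
    arrays = {f"p{i}_{p.name}": p.v for i, p in enumerate(params)}
    if extras:
        arrays.update({f"x_{k}": v for k, v in extras.items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    if config is not None:
        path.with_suffix(".json").write_text(json.dumps(config, indent=2, default=str))


def load_params(path, params: list[Param]) -> None:
    """Load values saved by :func:`save_params` into ``params`` in order."""
    data = np.load(Path(path).with_suffix(".npz"))
    for i, p in enumerate(params):
        key = f"p{i}_{p.name}"
        p.v[...] = data[key]
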