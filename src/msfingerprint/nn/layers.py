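"""Minimal numpy neural-network building blocks with manual backprop.

Just enough machinery for small residual convolutional classifiers and
embedding networks over heatmap images: 3x3 same-padding convolutions,
batch normalization, ReLU, average pooling, fully connected layers, residual
blocks, Adam, and the two losses (softmax cross-entropy, triplet).  All
computation is float32 on CPU; determinism follows from seeding numpy.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or 1x1) convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.pad = kernel // 2

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, Wd = x.shape
        p = self.pad
        if p:
            xp = np.zeros((N, C, H + 2 * p, Wd + 2 * p), dtype=x.dtype)
            xp[:, :, p : p + H, p : p + Wd] = x
        else:
            xp = x
        self._xp_shape = xp.shape
        self._xp = xp
        k = self.kernel
        out = None
        for di in range(k):
            for dj in range(k):
                sl = xp[:, :, di : di + H, dj : dj + Wd]
                # (N,C,H,W) x (c_out,C) -> (N,H,W,c_out)
                contrib = np.tensordot(sl, self.W.value[:, :, di, dj], axes=([1], [1]))
                out = contrib if out is None else out + contrib
        out = out + self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, c_out, H, Wd = dy.shape
        dyt = dy.transpose(0, 2, 3, 1)  # (N,H,W,c_out)
        k, p = self.kernel, self.pad
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                sl = self._xp[:, :, di : di + H, dj : dj + Wd]
                self.W.grad[:, :, di, dj] += np.tensordot(
                    dyt, sl, axes=([0, 1, 2], [0, 2, 3])
                )
                dxp[:, :, di : di + H, dj : dj + Wd] += np.tensordot(
                    dyt, self.W.value[:, :, di, dj], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        self.b.grad += dyt.sum(axis=(0, 1, 2))
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        # standard batch-norm backward, per channel
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        self._cache = None
        return inv[None, :, None, None] * (term1 - term2 - term3)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class AvgPool2d(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        s = self.size
        if H % s or W % s:
            raise ValueError(f"spatial dims {(H, W)} not divisible by {s}")
        self._shape = x.shape
        return x.reshape(N, C, H // s, s, W // s, s).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.size
        up = np.repeat(np.repeat(dy, s, axis=2), s, axis=3) / (s * s)
        return up.astype(np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (H * W)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, std, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        x = self._x
        self._x = None
        return dy @ self.W.value


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus (projected) identity, then ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.project = None
        if c_in != c_out:
            self.project = Conv2d(c_in, c_out, 1, rng)
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        ps = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.project is not None:
            ps += self.project.params()
        return ps

    def children(self) -> list[Layer]:
        kids = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.project is not None:
            kids.append(self.project)
        return kids + [self.relu_out]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        skip = x if self.project is None else self.project.forward(x, train)
        return self.relu_out.forward(h + skip, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.project is None:
            dx = dx + d
        else:
            dx = dx + self.project.backward(d)
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def children(self) -> list[Layer]:
        return list(self.layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def iter_layers(layer: Layer):
    """Depth-first iteration over a layer tree."""
    yield layer
    for child in layer.children():
        yield from iter_layers(child)


def calibrate_batchnorm(net: Layer, X: np.ndarray) -> None:
    """Re-estimate all BatchNorm running statistics from one full pass.

    Momentum-averaged statistics from small, class-balanced batches are a
    noisy estimate of the training-set statistics; with few samples that
    noise visibly shifts eval-mode activations.  One forward pass with
    momentum forced to 1 pins the running statistics to the full-set values.
    """
    bns = [l for l in iter_layers(net) if isinstance(l, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    net.forward(X.astype(np.float32), train=True)
    for bn, m in zip(bns, saved):
        bn.momentum = m


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch; returns (loss, dloss/dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
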