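"""Minimal 3D neural-network layers with explicit forward/backward passes.

The survival classifier is small (three conv blocks, a dense head), so the
layers are implemented directly on NumPy: convolution via sliding-window
views contracted with ``tensordot`` (BLAS matmul underneath), max-pooling
via argmax bookkeeping, batch norm with the standard analytic gradient.
Gradient correctness is verified against central finite differences in the
test suite.

Array convention: channels last, ``(N, X, Y, Z, C)``; all layers are
stride-1 "same"-padded or non-overlapping pools.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv3D", "BatchNorm3D", "ReLU", "Dropout", "MaxPool3D",
    "Flatten", "Dense", "softmax", "softmax_cross_entropy", "SGDMomentum",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv3D(Layer):
    """Stride-1 3D convolution with odd kernel and zero "same" padding.

    Computed by shift-and-matmul: one (voxels x Cin) @ (Cin x Cout) product
    per kernel offset on a shifted view of the padded input, which avoids
    materializing the full im2col window tensor. Backward uses the exact
    adjoint of the same decomposition. The layer that touches the raw input
    can set ``skip_input_grad`` since no earlier layer consumes its input
    gradient.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 rng: np.random.Generator | None = None,
                 dtype=np.float32, skip_input_grad: bool = False):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError(f"kernel dims must be odd, got {kernel}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(kernel))
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal(kernel + (in_channels, out_channels)) * std
                  ).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.skip_input_grad = skip_input_grad
        self._cache = None

    def _pad(self, x):
        kx, ky, kz = self.kernel
        return np.pad(x, [(0, 0), (kx // 2,) * 2, (ky // 2,) * 2, (kz // 2,) * 2,
                          (0, 0)])

    def forward(self, x, training=False, rng=None):
        kx, ky, kz = self.kernel
        N, X, Y, Z, _ = x.shape
        xp = self._pad(x)
        out = np.zeros((N, X, Y, Z, self.out_channels), dtype=x.dtype)
        for dx in range(kx):
            for dy in range(ky):
                for dz in range(kz):
                    view = xp[:, dx:dx + X, dy:dy + Y, dz:dz + Z, :]
                    out += view @ self.W[dx, dy, dz]
        out += self.b
        self._cache = (xp, x.shape) if training else None
        return out

    def backward(self, grad):
        if self._cache is None:
            raise RuntimeError("backward called without a training forward pass")
        xp, in_shape = self._cache
        self._cache = None
        kx, ky, kz = self.kernel
        N, X, Y, Z, _ = in_shape
        gf = grad.reshape(-1, self.out_channels)
        self.db += gf.sum(axis=0).astype(self.b.dtype)
        need_dx = not self.skip_input_grad
        dxp = np.zeros_like(xp) if need_dx else None
        for dx in range(kx):
            for dy in range(ky):
                for dz in range(kz):
                    view = xp[:, dx:dx + X, dy:dy + Y, dz:dz + Z, :]
                    self.dW[dx, dy, dz] += (
                        view.reshape(-1, self.in_channels).T @ gf
                    ).astype(self.W.dtype)
                    if need_dx:
                        dxp[:, dx:dx + X, dy:dy + Y, dz:dz + Z, :] += (
                            grad @ self.W[dx, dy, dz].T)
        if not need_dx:
            return np.zeros(in_shape, dtype=grad.dtype)
        px, py, pz = kx // 2, ky // 2, kz // 2
        dx_full = dxp[:, px:px + X, py:py + Y, pz:pz + Z, :]
        return np.ascontiguousarray(dx_full, dtype=grad.dtype)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm3D(Layer):
    """Per-channel batch normalization over the (N, X, Y, Z) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, training=False, rng=None):
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.astype(np.float64))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.astype(np.float64))
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std.astype(x.dtype))
        return (self.gamma * xhat + self.beta).astype(x.dtype)

    def backward(self, grad):
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 1, 2, 3)
        m = float(np.prod([grad.shape[a] for a in axes]))
        self.dgamma += (grad * xhat).sum(axis=axes).astype(self.gamma.dtype)
        self.dbeta += grad.sum(axis=axes).astype(self.beta.dtype)
        g = grad * self.gamma
        dx = (g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / m) * inv_std
        return dx.astype(grad.dtype)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False, rng=None):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad):
        mask, self._mask = self._mask, None
        return grad * mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None if not training else np.float32(1.0)
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._mask = mask.astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        mask, self._mask = self._mask, None
        return grad * mask


class MaxPool3D(Layer):
    """Non-overlapping max pool; trailing voxels beyond a multiple of the
    pool size are dropped (floor semantics)."""

    def __init__(self, size: int = 2):
        self.size = int(size)
        self._cache = None

    def _out_dims(self, shape):
        return tuple(d // self.size for d in shape[1:4])

    def forward(self, x, training=False, rng=None):
        p = self.size
        n, X, Y, Z, c = x.shape
        ox, oy, oz = self._out_dims(x.shape)
        xc = x[:, :ox * p, :oy * p, :oz * p, :]
        r = xc.reshape(n, ox, p, oy, p, oz, p, c)
        r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(n, ox, oy, oz, c, p ** 3)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, idx)
        return out

    def backward(self, grad):
        in_shape, idx = self._cache
        self._cache = None
        p = self.size
        n, X, Y, Z, c = in_shape
        ox, oy, oz = X // p, Y // p, Z // p
        g = np.zeros((n, ox, oy, oz, c, p ** 3), dtype=grad.dtype)
        np.put_along_axis(g, idx[..., None], grad[..., None], axis=-1)
        g = g.reshape(n, ox, oy, oz, c, p, p, p).transpose(0, 1, 5, 2, 6, 3, 7, 4)
        g = g.reshape(n, ox * p, oy * p, oz * p, c)
        dx = np.zeros(in_shape, dtype=grad.dtype)
        dx[:, :ox * p, :oy * p, :oz * p, :] = g
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.W = (rng.standard_normal((in_features, out_features)) * std).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        if training:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, grad):
        x, self._cache = self._cache, None
        self.dW += (x.T @ grad).astype(self.W.dtype)
        self.db += grad.sum(axis=0).astype(self.b.dtype)
        return (grad @ self.W.T).astype(grad.dtype)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class SGDMomentum:
    """Classic momentum: v <- mu v - lr g;  w <- w + v."""

    def __init__(self, layers: list[Layer], learning_rate: float, momentum: float):
        self.layers = layers
        self.lr = learning_rate
        self.mu = momentum
        self.velocity = [np.zeros_like(p) for layer in layers for p in layer.params()]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads():
                g[...] = 0

    def step(self) -> None:
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                v = self.velocity[i]
                v *= self.mu
                v -= self.lr * g
                p += v
                i += 1
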