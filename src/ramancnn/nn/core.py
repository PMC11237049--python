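"""Layer primitives with explicit forward/backward passes.

Every layer caches what its backward pass needs on ``forward`` and returns
the gradient with respect to its input from ``backward`` — gradients flow
all the way back to the network input, which is what path-integral
attribution requires.  All arithmetic is float64.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation) over (N, C_in, W) inputs.

    'same'-style zero padding of k//2 on both sides; optional stride.
    Convolutions feeding a batch-norm carry no bias.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = False, *,
                 rng: np.random.Generator, name: str = "conv") -> None:
        if kernel_size < 1 or stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_length(self, w_in: int) -> int:
        return (w_in + 2 * self.pad - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, w_in = x.shape
        k = self.kernel_size
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        w_out = self.out_length(w_in)
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        windows = windows[:, :, :: self.stride, :][:, :, :w_out, :]  # (N, C, W_out, k)
        # im2col matmul: (N*W_out, C*k) @ (C*k, O)
        cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(n * w_out, c * k)
        y = (cols @ self.weight.value.reshape(self.out_channels, c * k).T)
        y = y.reshape(n, w_out, self.out_channels).transpose(0, 2, 1)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None]
        self._cache = (x.shape, cols, w_out)
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, c, w_in), cols, w_out = self._cache
        k = self.kernel_size
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * w_out, self.out_channels)
        self.weight.grad += (g2.T @ cols).reshape(self.out_channels, c, k)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        # columns gradient back to input positions (col2im scatter-add per tap)
        dcols = (g2 @ self.weight.value.reshape(self.out_channels, c * k))
        dcols = dcols.reshape(n, w_out, c, k).transpose(0, 2, 1, 3)  # (N, C, W_out, k)
        dxp = np.zeros((n, c, w_in + 2 * self.pad))
        for j in range(k):
            dxp[:, :, j : j + self.stride * w_out : self.stride] += dcols[:, :, :, j]
        return dxp[:, :, self.pad : self.pad + w_in]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (N, C, W)."""

    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        if not train:
            # eval mode: mean/var are constants
            return g * inv[None, :, None]
        n_eff = shape[0] * shape[2]
        term = g - g.mean(axis=(0, 2), keepdims=True) - xhat * (g * xhat).mean(axis=(0, 2), keepdims=True)
        return term * inv[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        else:
            self._mask = 1.0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool1d(Layer):
    """(N, C, W) -> (N, C) mean over the spectral axis."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._w = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._w, axis=2) / self._w


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, name: str = "dense") -> None:
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and the gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
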