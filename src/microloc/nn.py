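"""Minimal NumPy neural-network layers with hand-written backprop.

Just enough machinery to exercise the imbalance-handling components on
CPU at small scale: valid (unpadded) strided convolution via im2col,
ReLU, dropout, linear layers, the adaptive concatenate pooling layer,
and SGD with momentum, weight decay and per-group learning rates.
Forward caches whatever backward needs; ``Sequential.backward`` returns
the gradient w.r.t. the input and accumulates parameter gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ReLU",
    "Dropout",
    "Linear",
    "ACPLayer",
    "Flatten",
    "Sequential",
    "SGD",
    "bce_with_logits",
    "bce_with_logits_grad",
    "sigmoid",
]


class Parameter:
    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """Valid convolution (no padding) with square kernel and stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.kernel_size = kernel_size

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s = self.kernel_size, self.stride
        b, c, h, w = x.shape
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        ho, wo = windows.shape[2], windows.shape[3]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho, wo, c * k * k)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = cols @ wmat.T + self.bias.value
        self._cache = (x.shape, cols)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (in_shape, cols) = self._cache
        b, c, h, w = in_shape
        k, s = self.kernel_size, self.stride
        g = grad.transpose(0, 2, 3, 1)  # (B, Ho, Wo, Oc)
        ho, wo = g.shape[1], g.shape[2]
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        self.weight.grad += (
            g.reshape(-1, g.shape[-1]).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(self.weight.value.shape)
        self.bias.grad += g.sum(axis=(0, 1, 2))
        gcols = (g @ wmat).reshape(b, ho, wo, c, k, k)
        gx = np.zeros(in_shape)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + s * ho : s, dj : dj + s * wo : s] += gcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class ACPLayer(Layer):
    """Adaptive concatenate pooling: global average + global max pooling
    concatenated along the channel axis, flattening (B, C, H, W) to
    (B, 2C) for any spatial size."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w)
        avg = flat.mean(axis=2)
        argmax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, argmax[:, :, None], axis=2)[:, :, 0]
        self._cache = (x.shape, argmax)
        return np.concatenate([avg, mx], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (shape, argmax) = self._cache
        b, c, h, w = shape
        gavg, gmax = grad[:, :c], grad[:, c:]
        gx = np.repeat(gavg[:, :, None], h * w, axis=2) / (h * w)
        np.put_along_axis(
            gx, argmax[:, :, None], np.take_along_axis(gx, argmax[:, :, None], axis=2) + gmax[:, :, None], axis=2
        )
        return gx.reshape(shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class SGD:
    """Stochastic gradient descent with momentum, weight decay and one
    learning rate per parameter group (discriminative learning rates)."""

    def __init__(
        self,
        param_groups: list[list[Parameter]],
        lrs: list[float],
        momentum: float = 0.9,
        weight_decay: float = 1e-6,
    ) -> None:
        if len(param_groups) != len(lrs):
            raise ValueError("one learning rate per parameter group required")
        self.param_groups = param_groups
        self.lrs = list(lrs)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [[np.zeros_like(p.value) for p in g] for g in param_groups]

    def set_lrs(self, lrs) -> None:
        lrs = list(np.atleast_1d(lrs))
        if len(lrs) != len(self.param_groups):
            raise ValueError("one learning rate per parameter group required")
        self.lrs = [float(lr) for lr in lrs]

    def step(self) -> None:
        for group, lr, vel in zip(self.param_groups, self.lrs, self._velocity):
            for p, v in zip(group, vel):
                g = p.grad + self.weight_decay * p.value
                v *= self.momentum
                v -= lr * g
                p.value += v

    def zero_grad(self) -> None:
        for group in self.param_groups:
            for p in group:
                p.zero_grad()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Numerically stable elementwise BCE on raw scores."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    return np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))


def bce_with_logits_grad(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d BCE / d logit = sigmoid(z) - y."""
    return sigmoid(np.asarray(logits, dtype=np.float64)) - np.asarray(targets, dtype=np.float64)
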