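"""A compact numpy implementation of the 3D convolutional network machinery.

Provides exactly the pieces the context-explanation model needs: 3D
convolution (odd kernels, same-padding for k>1), 2x average pooling, ReLU,
flatten, affine layers, stochastic gradient descent with momentum and weight
decay, and a step learning-rate schedule. Forward passes cache what the
backward pass needs; evaluation-mode forwards are deterministic pure
functions of the parameters.

Parameters are initialized Kaiming-uniform (fan-in scaled) from a seeded
generator, so construction is bitwise reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "AvgPool3d", "ReLU", "Flatten", "Linear", "Sequential",
           "SGD", "StepLR"]

DTYPE = np.float64


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def out_shape(self, in_shape):
        c, d = in_shape
        return (c * d ** 3,)


class AvgPool3d(Layer):
    """Non-overlapping average pooling; spatial dims must divide the stride."""

    def __init__(self, stride: int = 2):
        self.stride = stride

    def forward(self, x, train=False):
        s = self.stride
        b, c, d, h, w = x.shape
        if d % s or h % s or w % s:
            raise ValueError(f"spatial dims {(d, h, w)} not divisible by pool stride {s}")
        self._in_shape = x.shape
        return x.reshape(b, c, d // s, s, h // s, s, w // s, s).mean(axis=(3, 5, 7))

    def backward(self, grad):
        s = self.stride
        g = grad[:, :, :, None, :, None, :, None] / s ** 3
        g = np.broadcast_to(g, grad.shape[:2] + (grad.shape[2], s, grad.shape[3], s,
                                                 grad.shape[4], s))
        return g.reshape(self._in_shape)

    def out_shape(self, in_shape):
        c, d = in_shape
        if d % self.stride:
            raise ValueError(f"grid dim {d} not divisible by pool stride {self.stride}")
        return (c, d // self.stride)


class Conv3d(Layer):
    """3D convolution with odd kernel and same-padding (pad = (k-1)//2)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.pad = (kernel - 1) // 2
        fan_in = in_channels * kernel ** 3
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_channels, fan_in)).astype(DTYPE),
            f"{name}.weight")
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels).astype(DTYPE),
                              f"{name}.bias")

    def parameters(self):
        return [self.weight, self.bias]

    def out_shape(self, in_shape):
        c, d = in_shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        return (self.cout, d)

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        # windows: (B, Cin, D, H, W, k, k, k) -> columns (B*DHW, Cin*k^3)
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        cols = view.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b * d * h * w, c * k ** 3)
        self._cols, self._spatial, self._batch = cols, (d, h, w), b
        out = cols @ self.weight.value.T + self.bias.value
        return out.reshape(b, d, h, w, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, grad):
        b, (d, h, w) = self._batch, self._spatial
        k, p, c = self.k, self.pad, self.cin
        gmat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, self.cout)
        self.weight.grad += gmat.T @ self._cols
        self.bias.grad += gmat.sum(axis=0)
        dcols = (gmat @ self.weight.value).reshape(b, d, h, w, c, k, k, k)
        dxp = np.zeros((b, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i:i + d, j:j + h, l:l + w] += \
                        dcols[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
        return dxp[:, :, p:p + d, p:p + h, p:p + w] if p else dxp


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "linear"):
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_features, in_features)).astype(DTYPE),
            f"{name}.weight")
        self.bias = Parameter(rng.uniform(-bound, bound, out_features).astype(DTYPE),
                              f"{name}.bias")

    def parameters(self):
        return [self.weight, self.bias]

    def out_shape(self, in_shape):
        return (self.weight.value.shape[0],)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape


class SGD:
    """Stochastic gradient descent with momentum and (decoupled-from-loss) L2
    weight decay, following the torch convention: g <- g + wd*p; v <- mu*v + g;
    p <- p - lr*v."""

    def __init__(self, parameters: list[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.parameters = parameters
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.value) for p in parameters]

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.parameters, self._velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v


class StepLR:
    """Multiply the learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: SGD, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.step_size, self.gamma = step_size, gamma

    def lr_at(self, epoch: int) -> float:
        return self.base_lr * self.gamma ** (epoch // self.step_size)

    def set_epoch(self, epoch: int):
        self.optimizer.lr = self.lr_at(epoch)
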