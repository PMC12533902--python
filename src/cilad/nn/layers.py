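"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as ``Tensor``s with ``requires_grad=True`` and
expose ``params()`` for the optimizer.  Stochastic layers (dropout) draw
from an explicit ``numpy.random.Generator`` so training is seedable.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, maxpool1d


class Layer:
    def params(self) -> list[Tensor]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class Conv1D(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 pad: int = 0):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Tensor(rng.normal(0, scale, (c_out, c_in, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = pad
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b, pad=self.pad)

    def params(self):
        return [self.W, self.b]


class MaxPool1D(Layer):
    def __init__(self, size: int, stride: int | None = None, pad: int = 0):
        self.size, self.stride, self.pad = size, stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.size, self.stride, self.pad)


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class BatchNorm1D(Layer):
    """Batch normalization over channels of (B, C, L) activations."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1))
        self.running_var = np.ones((1, channels, 1))
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) \
                * Tensor((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class LSTM(Layer):
    """Single-layer LSTM; consumes (B, T, F), returns the final hidden state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_hidden)
        self.Wx = Tensor(rng.normal(0, scale, (n_in, 4 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0, scale, (n_hidden, 4 * n_hidden)), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        # all input projections in one matmul; the recurrence adds h @ Wh
        xproj = (x.reshape(B * T, F) @ self.Wx + self.b).reshape(B, T, 4 * H)
        for t in range(T):
            z = xproj[:, t, :] + h @ self.Wh
            i = z[:, 0:H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    def params(self):
        return [self.Wx, self.Wh, self.b]


class Inception1D(Layer):
    """GoogLeNet-style 1-D block: parallel 1/3/5 convolutions plus a pooled
    1x1 branch, channel-concatenated; 'same' padding keeps lengths aligned."""

    def __init__(self, c_in: int, branch: int, rng: np.random.Generator):
        self.b1 = Conv1D(c_in, branch, 1, rng)
        self.b3 = Conv1D(c_in, branch, 3, rng, pad=1)
        self.b5 = Conv1D(c_in, branch, 5, rng, pad=2)
        self.pool = MaxPool1D(3, stride=1, pad=1)
        self.bp = Conv1D(c_in, branch, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y1 = self.b1(x).relu()
        y3 = self.b3(x).relu()
        y5 = self.b5(x).relu()
        yp = self.bp(self.pool(x)).relu()
        return concat([y1, y3, y5, yp], axis=1)

    def params(self):
        return (self.b1.params() + self.b3.params() + self.b5.params()
                + self.bp.params())
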