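"""A small reverse-mode automatic-differentiation core over NumPy arrays.

Only the operations the package's networks need are implemented: broadcasted
arithmetic, matmul, shape ops, reductions, the usual nonlinearities,
log-softmax, valid/padded 1-D convolution and 1-D max pooling.  Gradients
accumulate in ``Tensor.grad`` after :meth:`Tensor.backward`.

A module-level ``no_grad()`` context disables graph construction for cheap
inference passes (e.g. policy rollouts).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float32  # single precision, the conventional deep-learning default


def set_default_dtype(dtype) -> None:
    """Set the array dtype for new Tensors (float32 default; float64 for
    high-precision work such as numeric gradient checking)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


@contextmanager
def default_dtype(dtype):
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _sum_to_shape(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if (_GRAD_ENABLED and self.requires_grad) else ()
        self._backward = backward if (_GRAD_ENABLED and self.requires_grad) else None

    # -- graph -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        g = _sum_to_shape(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out._parents:
            def bw(g):
                self._accum(g)
                other._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out._parents:
            def bw(g):
                self._accum(g * other.data)
                other._accum(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out._parents:
            def bw(g):
                self._accum(g @ np.swapaxes(other.data, -1, -2))
                other._accum(np.swapaxes(self.data, -1, -2) @ g)
            out._backward = bw
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        if out._parents:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out._parents:
            basic = isinstance(idx, (int, slice)) or (
                isinstance(idx, tuple)
                and all(isinstance(k, (int, slice)) for k in idx))
            def bw(g):
                full = np.zeros_like(self.data)
                if basic:  # no repeated positions: plain assignment suffices
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out._parents:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)
        out = Tensor(out_data, parents=(self,))
        if out._parents:
            def bw(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
                self._accum(full)
            out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * (1.0 - y ** 2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(y, parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out._parents:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, parents=(self,))
        if out._parents:
            soft = np.exp(ls)
            def bw(g):
                self._accum(g - soft * g.sum(axis=axis, keepdims=True))
            out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)
        out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): x (B, Cin, L), w (Cout, Cin, K).

    Zero-pads ``pad`` samples on both ends; output length L + 2*pad - K + 1.
    """
    B, Cin, L = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError("channel mismatch between input and kernel")
    Lp = L + 2 * pad
    if Lp < K:
        raise ValueError(f"input length {L} (padded {Lp}) shorter than kernel {K}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lout = Lp - K + 1
    # im2col: (B, Cin*K, Lout)
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,Cin,Lout,K)
    cols = win.transpose(0, 1, 3, 2).reshape(B, Cin * K, Lout)
    W2 = w.data.reshape(Cout, Cin * K)
    out_data = np.matmul(W2, cols)  # (B, Cout, Lout)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)
    if out._parents:
        def bw(g):
            gw = np.einsum("bol,bfl->of", g, cols, optimize=True)
            w._accum(gw.reshape(Cout, Cin, K))
            if b is not None:
                b._accum(g.sum(axis=(0, 2)))
            dcols = np.matmul(W2.T, g)  # (B, Cin*K, Lout)
            dcols = dcols.reshape(B, Cin, K, Lout)
            dxp = np.zeros((B, Cin, Lp))
            for j in range(K):
                dxp[:, :, j:j + Lout] += dcols[:, :, j, :]
            x._accum(dxp[:, :, pad:Lp - pad] if pad else dxp)
        out._backward = bw
    return out


def maxpool1d(x: Tensor, size: int, stride: int | None = None, pad: int = 0) -> Tensor:
    """1-D max pooling over the last axis of x (B, C, L)."""
    stride = stride or size
    B, C, L = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)), constant_values=-np.inf) \
        if pad else x.data
    Lp = L + 2 * pad
    if Lp < size:
        raise ValueError(f"input length {L} (padded {Lp}) shorter than pool {size}")
    win = np.lib.stride_tricks.sliding_window_view(xp, size, axis=2)[:, :, ::stride, :]
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))
    if out._parents:
        Lout = out_data.shape[2]
        def bw(g):
            dx = np.zeros((B, C, Lp))
            bb, cc, tt = np.meshgrid(np.arange(B), np.arange(C), np.arange(Lout),
                                     indexing="ij")
            pos = tt * stride + idx
            np.add.at(dx, (bb, cc, pos), g)
            x._accum(dx[:, :, pad:Lp - pad] if pad else dx)
        out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            denom = np.sqrt(v / (1 - self.beta2 ** self.t))
            denom += self.eps
            p.data -= (self.lr / (1 - self.beta1 ** self.t)) * m / denom

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
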