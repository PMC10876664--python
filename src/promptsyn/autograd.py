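"""A small reverse-mode automatic-differentiation engine over NumPy arrays.

Supports exactly the operations the transformer backbone and the attention
baseline need: broadcasting arithmetic, batched matrix products, reductions,
elementwise transcendentals, embedding lookup, basic-index slicing and
concatenation, plus composite softmax / layer-norm / GELU helpers and a
decoupled-weight-decay Adam optimizer.  Gradients are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "embedding",
    "concat",
    "masked_softmax",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "layer_norm",
    "gelu",
    "relu",
    "no_grad",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- ops --------------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = _node(self.data**exponent, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    def exp(self):
        value = np.exp(self.data)
        out = _node(value, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * value)

        out._backward = bw
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = _node(value, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - value**2))

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, axes):
        inverse = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose(tuple(reversed(range(self.data.ndim))))

    def clip_min(self, floor: float):
        """Elementwise max(x, floor); gradient is blocked below the floor."""
        mask = self.data > floor
        out = _node(np.where(mask, self.data, floor), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = _node(self.data[key], (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accumulate(full)

        out._backward = bw
        return out


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_tensor(value, like: np.ndarray | None = None) -> Tensor:
    if isinstance(value, Tensor):
        return value
    arr = np.asarray(value)
    # keep scalar constants from promoting a float32 graph to float64
    if like is not None and arr.ndim == 0 and arr.dtype != like.dtype:
        arr = arr.astype(like.dtype)
    return Tensor(arr)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = np.asarray(data)
    out.grad = None
    out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out._parents = parents if out.requires_grad else ()
    out._backward = None
    return out


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=False)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    indices = np.asarray(indices)
    out = _node(weight.data[indices], (weight,))

    def bw(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, indices.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
            weight._accumulate(full)

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def masked_softmax(scores: Tensor, allowed: np.ndarray | None, scale: float = 1.0) -> Tensor:
    """Fused ``softmax(scale * scores + mask)`` along the last axis.

    ``allowed`` is a boolean array broadcastable to ``scores``; disallowed
    entries get probability exactly 0 (a fully-masked row yields all zeros).
    Fusing the scale/mask/normalize chain into one node keeps the number of
    full passes over the (B, heads, L, L) attention array small.
    """
    z = scores.data * scale
    m = z.max(axis=-1, keepdims=True)
    e = np.exp(np.minimum(z - m, 0.0))
    if allowed is not None:
        e = np.where(allowed, e, 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    p = e / np.maximum(denom, np.finfo(e.dtype).tiny)
    out = _node(p, (scores,))

    def bw(g):
        if scores.requires_grad:
            inner = (g * p).sum(axis=-1, keepdims=True)
            scores._accumulate(scale * p * (g - inner))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # The shift is clipped at -60: exp(-60) is negligible against the max
    # term's exp(0) = 1, stays clear of subnormal slow paths, and cuts the
    # gradient of entries that are additively masked to huge negatives.
    shifted = (x - constant(x.data.max(axis=axis, keepdims=True))).clip_min(-60.0)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = constant(x.data.max(axis=axis, keepdims=True))
    lse = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    return x - lse


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels, dtype=int)
    n, k = logits.data.shape
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -(log_softmax(logits) * constant(onehot)).sum() * (1.0 / n)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps).pow(-0.5) * gain + bias


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    inner = (x + x * x * x * 0.044715) * _GELU_C
    return x * (inner.tanh() + 1.0) * 0.5


def relu(x: Tensor) -> Tensor:
    mask = constant((x.data > 0).astype(x.data.dtype))
    return x * mask


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied only to matrix-shaped parameters (ndim >= 2);
    biases and layer-norm gains are exempt, the usual transformer practice.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update
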