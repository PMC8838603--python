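"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the feed-forward and message-passing
classifiers need: dense algebra (matmul, add, mul, relu, concat), segment
reductions for graph pooling (segment_sum, segment_max, gather_rows) and a
numerically stable binary cross-entropy on logits. Gradients flow through a
topologically sorted tape; ties in segment_max split their gradient evenly.
"""
from __future__ import annotations

import numpy as np


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self._backward = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.data) if node.requires_grad else None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.requires_grad:
                node._backward()

    # convenience operators ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul_const(other, -1.0))

    def __mul__(self, other):
        return mul(self, other)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(node, grad):
    if node.requires_grad:
        # reverse numpy broadcasting of `grad` onto node.data's shape
        while grad.ndim > node.data.ndim:
            grad = grad.sum(axis=0)
        for axis, size in enumerate(node.data.shape):
            if size == 1 and grad.shape[axis] != 1:
                grad = grad.sum(axis=axis, keepdims=True)
        node.grad += grad


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def _backward():
        _accumulate(a, out.grad)
        _accumulate(b, out.grad)

    out._backward = _backward
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def _backward():
        _accumulate(a, out.grad * b.data)
        _accumulate(b, out.grad * a.data)

    out._backward = _backward
    return out


def mul_const(a, c: float):
    a = _as_tensor(a)
    out = Tensor(a.data * c, parents=(a,))

    def _backward():
        _accumulate(a, out.grad * c)

    out._backward = _backward
    return out


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def _backward():
        _accumulate(a, out.grad @ b.data.T)
        _accumulate(b, a.data.T @ out.grad)

    out._backward = _backward
    return out


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))

    def _backward():
        _accumulate(a, out.grad * mask)

    out._backward = _backward
    return out


def concat_cols(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))
    split = a.data.shape[1]

    def _backward():
        _accumulate(a, out.grad[:, :split])
        _accumulate(b, out.grad[:, split:])

    out._backward = _backward
    return out


def gather_rows(a, index):
    a = _as_tensor(a)
    index = np.asarray(index, dtype=int)
    out = Tensor(a.data[index], parents=(a,))

    def _backward():
        grad = np.zeros_like(a.data)
        np.add.at(grad, index, out.grad)
        _accumulate(a, grad)

    out._backward = _backward
    return out


def segment_sum(a, index, n_segments: int):
    """Row-wise scatter-add: out[s] = sum of a[i] with index[i] == s."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=int)
    data = np.zeros((n_segments, a.data.shape[1]))
    np.add.at(data, index, a.data)
    out = Tensor(data, parents=(a,))

    def _backward():
        _accumulate(a, out.grad[index])

    out._backward = _backward
    return out


def segment_max(a, index, n_segments: int):
    """Row-wise scatter-max; empty segments yield 0, ties share gradient."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=int)
    data = np.full((n_segments, a.data.shape[1]), -np.inf)
    np.maximum.at(data, index, a.data)
    empty = np.isinf(data)
    data[empty] = 0.0
    out = Tensor(data, parents=(a,))

    def _backward():
        is_max = (a.data == out.data[index]) & ~empty[index]
        counts = np.zeros((n_segments, a.data.shape[1]))
        np.add.at(counts, index, is_max.astype(float))
        share = np.where(is_max, 1.0 / np.maximum(counts[index], 1.0), 0.0)
        _accumulate(a, out.grad[index] * share)

    out._backward = _backward
    return out


def dropout(a, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; pass rng=None (or rate 0) to disable at inference."""
    if rng is None or rate <= 0.0:
        return a
    a = _as_tensor(a)
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def sigmoid(a):
    a = _as_tensor(a)
    s = 0.5 * (1.0 + np.tanh(0.5 * a.data))
    out = Tensor(s, parents=(a,))

    def _backward():
        _accumulate(a, out.grad * s * (1.0 - s))

    out._backward = _backward
    return out


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on logits; targets is a constant 0/1 array."""
    logits = _as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))

    def _backward():
        p = 0.5 * (1.0 + np.tanh(0.5 * z))
        _accumulate(logits, out.grad * (p - y) / y.size)

    out._backward = _backward
    return out


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Parameter:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-scale, scale, size=(fan_in, fan_out)))


class RMSprop:
    """RMSprop with plateau-style external LR control (set ``.lr``)."""

    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, c in zip(self.params, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            m_hat = m / (1.0 - self.beta1 ** self.t)
            v_hat = v / (1.0 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
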