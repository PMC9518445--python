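"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the fusion classifier needs (affine maps,
gating nonlinearities, concatenation, column slicing, dropout scaling and a
class-weighted softmax cross-entropy head) plus an Adam optimizer.  Gradients
are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "add",
    "mul",
    "sigmoid",
    "tanh",
    "relu",
    "selu",
    "concat",
    "cols",
    "weighted_softmax_cross_entropy",
    "softmax",
    "Adam",
]

# SELU constants (self-normalizing networks)
_SELU_LAMBDA = 1.0507009873554804934193349852946
_SELU_ALPHA = 1.6732632423543772848170429916717


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Accumulate gradients into every upstream tensor with requires_grad."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative post-order: graphs are deep for long sequences
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward):
    if _needs_graph(*parents):
        return Tensor(data, parents=tuple(parents), backward=backward)
    return Tensor(data)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(grad, out=None):
        a._accumulate(grad @ b.data.T)
        b._accumulate(a.data.T @ grad)

    return _make(out_data, (a, b), backward)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.data.shape))
        b._accumulate(_unbroadcast(grad, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
        b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(grad):
        x._accumulate(grad * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    out_data = np.tanh(x.data)

    def backward(grad):
        x._accumulate(grad * (1.0 - out_data * out_data))

    return _make(out_data, (x,), backward)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    out_data = np.maximum(x.data, 0.0)

    def backward(grad):
        x._accumulate(grad * (x.data > 0.0))

    return _make(out_data, (x,), backward)


def selu(x) -> Tensor:
    x = _as_tensor(x)
    pos = x.data > 0.0
    exp_x = np.exp(np.minimum(x.data, 0.0))
    out_data = _SELU_LAMBDA * np.where(pos, x.data, _SELU_ALPHA * (exp_x - 1.0))

    def backward(grad):
        deriv = _SELU_LAMBDA * np.where(pos, 1.0, _SELU_ALPHA * exp_x)
        x._accumulate(grad * deriv)

    return _make(out_data, (x,), backward)


def concat(tensors, axis=1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * grad.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(idx)])

    return _make(out_data, tensors, backward)


def cols(x, start, stop) -> Tensor:
    """Column slice x[:, start:stop] with gradient routing."""
    x = _as_tensor(x)
    out_data = x.data[:, start:stop]

    def backward(grad):
        full = np.zeros_like(x.data)
        full[:, start:stop] = grad
        x._accumulate(full)

    return _make(out_data, (x,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax over the last axis (inference path)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_softmax_cross_entropy(logits, labels, sample_weights=None) -> Tensor:
    """Mean of per-sample weighted cross-entropy on softmax outputs.

    ``labels`` are integer class indices; ``sample_weights`` multiply each
    sample's loss term (cost-sensitive learning).  The mean is over samples.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    n, k = logits.data.shape
    if sample_weights is None:
        sample_weights = np.ones(n)
    w = np.asarray(sample_weights, dtype=np.float64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    logp = z - logsumexp[:, None]
    loss = -(w * logp[np.arange(n), labels]).mean()

    def backward(grad):
        probs = np.exp(logp)
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        logits._accumulate(grad * (w[:, None] * (probs - onehot)) / n)

    return _make(loss, (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
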