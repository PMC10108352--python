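"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``.  The op set is deliberately small: exactly what the
convolutional autoencoder and the causal transformer in this package need.

All computation is float64 numpy, so results are bit-reproducible for a
fixed seed on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "embedding",
    "straight_through",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _node(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p: float):
        d = self.data ** p
        return Tensor._node(d, (self,), lambda g: (g * p * self.data ** (p - 1),))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        return Tensor._node(self.data.reshape(shape), (self,), lambda g: (g.reshape(src),))

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._node(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        d = self.data.sum(axis=axis, keepdims=keepdims)
        src_shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, src_shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, src_shape).copy(),)

        return Tensor._node(d, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __getitem__(self, idx) -> "Tensor":
        src_shape = self.data.shape

        def backward(g):
            out = np.zeros(src_shape, dtype=np.float64)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._node(self.data[idx], (self,), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    d = a.data + b.data
    return Tensor._node(
        d, (a, b), lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))
    )


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    d = a.data * b.data
    return Tensor._node(
        d,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    d = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor._node(d, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    return Tensor._node(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    d = x.data
    s = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))), np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    return Tensor._node(s, (x,), lambda g: (g * s * (1.0 - s),))


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    e = np.exp(x.data)
    return Tensor._node(e, (x,), lambda g: (g * e,))


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor._node(np.log(x.data), (x,), lambda g: (g / x.data,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

    return Tensor._node(s, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    s = np.exp(out)

    def backward(g):
        return (g - s * g.sum(axis=axis, keepdims=True),)

    return Tensor._node(out, (x,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `targets` under `logits`.

    `logits` has shape (..., K); `targets` the matching leading shape.
    """
    logits = _as_tensor(logits)
    targets = np.asarray(targets)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    flat_lp = logp.reshape(-1, logp.shape[-1])
    flat_t = targets.reshape(-1)
    n = flat_t.shape[0]
    picked = flat_lp[np.arange(n), flat_t]
    loss = -picked.mean()
    probs = np.exp(flat_lp)

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), flat_t] -= 1.0
        grad *= float(g) / n
        return (grad.reshape(logits.data.shape),)

    return Tensor._node(np.asarray(loss), (logits,), backward)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup `weight[idx]` with scatter-add backward into the table."""
    weight = _as_tensor(weight)
    idx = np.asarray(idx)

    def backward(g):
        out = np.zeros_like(weight.data)
        np.add.at(out, idx.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        return (out,)

    return Tensor._node(weight.data[idx], (weight,), backward)


def straight_through(z_e: Tensor, quantized: np.ndarray) -> Tensor:
    """Return `quantized` forward, but route gradients to `z_e` unchanged.

    This is the straight-through estimator used at the vector-quantization
    bottleneck: the quantizer is treated as the identity in the backward
    pass.
    """
    z_e = _as_tensor(z_e)
    q = np.asarray(quantized, dtype=np.float64)
    if q.shape != z_e.data.shape:
        raise ValueError(f"quantized shape {q.shape} != encoding shape {z_e.data.shape}")
    return Tensor._node(q, (z_e,), lambda g: (g,))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    d = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(d, tuple(tensors), backward)
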