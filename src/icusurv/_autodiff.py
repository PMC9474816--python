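"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the recurrent survival network: broadcasting
add/mul, matmul, sigmoid/tanh/log, embedding gather, slicing, concatenation
and reductions, plus an Adam optimizer. Everything is float64 and CPU-only,
which keeps training bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        def backward(g):
            return (g @ other.data.T, self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def sigmoid(self) -> "Tensor":
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        def backward(g):
            return (g * out_data * (1.0 - out_data),)
        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def log(self) -> "Tensor":
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        return self._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def sum(self, axis=None) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis), self.shape).copy(),)
        return self._make(self.data.sum(axis=axis), (self,), backward)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def slice_axis1(self, i: int) -> "Tensor":
        """Select index i along axis 1 (e.g. one sequence step of (B,T,F))."""
        def backward(g):
            full = np.zeros(self.shape)
            full[:, i] = g
            return (full,)
        return self._make(self.data[:, i], (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g):
            return tuple(np.split(g, splits, axis=axis))
        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
        )

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Embedding gather: rows of a (V, D) matrix at integer index array
        ``idx`` (any shape) → output of shape idx.shape + (D,)."""
        idx = np.asarray(idx)
        def backward(g):
            full = np.zeros(self.shape)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, self.shape[-1]))
            return (full,)
        return self._make(self.data[idx], (self,), backward)

    # -- backprop ---------------------------------------------------------
    def backward(self) -> None:
        assert self.data.ndim == 0, "backward() on scalars only"
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.ones(())}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf parameter
                node.grad = g if node.grad is None else node.grad + g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
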