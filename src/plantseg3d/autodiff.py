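"""A small reverse-mode automatic-differentiation core over numpy.

Just enough machinery to express and train the segmentation network: a
``Tensor`` wrapping a float64 ndarray, a tape of primitive ops with
broadcasting-aware gradients, and ``backward()`` doing a topological sweep.
Discrete choices (k-NN graphs, sampling indices, argmax) are treated as
constants of the graph, which is the usual convention for point-cloud
networks.

Primitives: + - * / @, power, exp, log, sqrt, relu, sigmoid, tanh, sum, mean,
max, maximum(0-hinges via relu), concatenate, reshape, take (fancy row
gather), log_softmax.  Everything is float64; this core favors testability
(finite-difference checks) over raw speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concatenate", "log_softmax", "softmax"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
            if node._backward is None:  # leaf: accumulate into .grad
                node.grad = g.copy() if node.grad is None else node.grad + g
                continue
            if node is self:
                node.grad = g.copy() if node.grad is None else node.grad + g
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else acc + pg

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
        while grad.ndim > len(shape):
            grad = grad.sum(axis=0)
        for ax, size in enumerate(shape):
            if size == 1 and grad.shape[ax] != 1:
                grad = grad.sum(axis=ax, keepdims=True)
        return grad.reshape(shape)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(out_data, parents=(self, other), backward=lambda g: (
            self._unbroadcast(g, self.shape), self._unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(self.data * other.data, parents=(self, other), backward=lambda g: (
            self._unbroadcast(g * other.data, self.shape),
            self._unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(self.data / other.data, parents=(self, other), backward=lambda g: (
            self._unbroadcast(g / other.data, self.shape),
            self._unbroadcast(-g * self.data / other.data**2, other.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        return Tensor(self.data ** exponent, parents=(self,), backward=lambda g: (
            g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                return g @ b.T, a.T @ g
            # batched last-two-dims matmul
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return self._unbroadcast(ga, a.shape), self._unbroadcast(gb, b.shape)

        return Tensor(out, parents=(self, other), backward=backward)

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(s, parents=(self,), backward=lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor(t, parents=(self,), backward=lambda g: (g * (1 - t**2),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor(e, parents=(self,), backward=lambda g: (g * e,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      backward=lambda g: (g / self.data,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor(r, parents=(self,), backward=lambda g: (g * 0.5 / r,))

    def clip_min(self, lo: float):
        """max(x, lo) with zero gradient below the floor (log clamping)."""
        mask = self.data > lo
        return Tensor(np.maximum(self.data, lo), parents=(self,),
                      backward=lambda g: (g * mask,))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape),)  # read-only view is fine
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape),)

        return Tensor(out, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax (ties)."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out = np.squeeze(out, axis=axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            return (grad,)

        return Tensor(out, parents=(self,), backward=backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: (g.reshape(old),))

    def take(self, indices: np.ndarray):
        """Row gather ``x[indices]`` (indices constant); scatter-add backward."""
        indices = np.asarray(indices)
        out = self.data[indices]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, indices.reshape(-1),
                      g.reshape(-1, *self.data.shape[1:]) if indices.ndim > 1 else g)
            return (grad,)

        return Tensor(out, parents=(self,), backward=backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward=backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)  # constant shift: exact for values, fine for grads
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
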