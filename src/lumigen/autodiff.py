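"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the conditional action model: dense linear algebra,
elementwise nonlinearities, row gather / segment sum for message passing, and
a numerically stable log-sum-exp.  Tapes are built eagerly; ``backward`` on a
scalar loss walks the graph once in reverse topological order.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "segment_sum", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(k for k, s in enumerate(shape) if s == 1 and grad.shape[k] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray | float,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out.backward_fn = bw
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out.backward_fn = bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self.data, other.data
        out = Tensor(a @ b, (self, other))

        def bw(g):
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 2:
                    self._accum(b @ g)
                elif a.ndim == 2 and b.ndim == 1:
                    self._accum(np.outer(g, b))
                elif a.ndim == 1 and b.ndim == 1:
                    self._accum(g * b)
                else:
                    self._accum(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 2:
                    other._accum(np.outer(a, g))
                elif a.ndim == 2 and b.ndim == 1:
                    other._accum(a.T @ g)
                elif a.ndim == 1 and b.ndim == 1:
                    other._accum(g * a)
                else:
                    other._accum(a.T @ g)

        out.backward_fn = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out.backward_fn = bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out.backward_fn = bw
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out.backward_fn = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out.backward_fn = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out.backward_fn = bw
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out.backward_fn = bw
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows: out[k] = self[idx[k]] (with repeats allowed)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        out.backward_fn = bw
        return out

    def take(self, idx: np.ndarray) -> "Tensor":
        """Flat element selection: out[k] = self.ravel()[idx[k]]."""
        idx = np.asarray(idx, dtype=np.intp)
        flat = self.data.reshape(-1)
        out = Tensor(flat[idx], (self,))

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(flat)
                np.add.at(acc, idx, g)
                self._accum(acc.reshape(self.data.shape))

        out.backward_fn = bw
        return out

    # -- autodiff ----------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A leaf tensor with gradients enabled."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out.backward_fn = bw
    return out


def segment_sum(x: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets: out[s] = sum x[seg==s]."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(data, seg_ids, x.data)
    out = Tensor(data, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g[seg_ids])

    out.backward_fn = bw
    return out


def logsumexp(x: Tensor) -> Tensor:
    """Stable log-sum-exp of a 1-D tensor (the constant shift carries no
    gradient, which is exact)."""
    c = float(np.max(x.data))
    return (x - c).exp().sum().log() + c


class Adam:
    """Standard Adam optimizer over a parameter list."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
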