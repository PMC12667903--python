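"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is a deliberately small engine — just the operations the invariant
graph encoder needs (dense affine maps, SiLU, gather/scatter over edge
indices, segment pooling, row normalization, softmax-style reductions) with
reverse-mode gradients.  Everything runs in float64 on CPU; gradient
correctness is covered by numeric-vs-analytic property tests.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Linear", "MLP", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``.

    Returns the input object itself when no reduction is needed, so callers
    can detect freshly allocated results with an identity check.
    """
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _scatter_add(idx: np.ndarray, values: np.ndarray, n_rows: int) -> np.ndarray:
    """Row scatter-add via sort + reduceat (much faster than np.ufunc.at)."""
    if values.ndim == 1:
        return np.bincount(idx, weights=values, minlength=n_rows).astype(values.dtype)
    order = np.argsort(idx, kind="stable")
    sidx = idx[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(sidx)) + 1])
    sums = np.add.reduceat(values[order], starts, axis=0)
    out = np.zeros((n_rows,) + values.shape[1:], dtype=values.dtype)
    out[sidx[starts]] = sums
    return out


class Tensor:
    """A NumPy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray | float,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(float)
        self.data = arr
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at many message layers
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # `own` promises the caller freshly allocated `grad` and holds no
        # other reference, so it can be adopted without a defensive copy
        if self.grad is None:
            self.grad = grad if own else np.array(grad)
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g: np.ndarray) -> None:
            gs = _unbroadcast(g, self.shape)
            self._accum(gs, own=gs is not g)
            go = _unbroadcast(g, other.shape)
            other._accum(go, own=go is not g)

        return Tensor(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, (self,), lambda g: self._accum(-g, own=True))

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: float) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g * other.data, self.shape), own=True)
            other._accum(_unbroadcast(g * self.data, other.shape), own=True)

        return Tensor(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g / other.data, self.shape), own=True)
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape), own=True)

        return Tensor(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            self._accum(g @ other.data.T, own=True)
            other._accum(self.data.T @ g, own=True)

        return Tensor(self.data @ other.data, (self, other), bwd)

    # -- shape / indexing ---------------------------------------------------

    @property
    def T(self) -> "Tensor":
        return Tensor(self.data.T, (self,), lambda g: self._accum(g.T))

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx)

        def bwd(g: np.ndarray) -> None:
            self._accum(_scatter_add(idx, g, len(self.data)), own=True)

        return Tensor(self.data[idx], (self,), bwd)

    def segment_sum(self, segments: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows into ``n_segments`` buckets (scatter-add by segment id)."""
        segments = np.asarray(segments)
        out = _scatter_add(segments, self.data, n_segments)
        return Tensor(out, (self,), lambda g: self._accum(g[segments], own=True))

    # -- reductions & nonlinearities ----------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy(), own=True)
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis) if not keepdims else g, self.shape).copy(), own=True)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor(out_data, (self,), lambda g: self._accum(g * out_data, own=True))

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), (self,), lambda g: self._accum(g / self.data, own=True))

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)
        return Tensor(out_data, (self,), lambda g: self._accum(g * 0.5 / out_data, own=True))

    def silu(self) -> "Tensor":
        # numerically stable sigmoid: never exponentiates a positive argument
        x = self.data
        sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bwd(g: np.ndarray) -> None:
            self._accum(g * sig * (1.0 + self.data * (1.0 - sig)), own=True)

        return Tensor(self.data * sig, (self,), bwd)

    def normalize_rows(self, eps: float = 1e-12) -> "Tensor":
        norm = (self * self).sum(axis=-1, keepdims=True).sqrt() + eps
        return self / norm


def _as_tensor(x: "Tensor | float | np.ndarray") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# layers and optimizer


class Linear:
    """Affine map with Kaiming-scaled Gaussian init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(scale=np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = Tensor(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Two-layer perceptron with SiLU activation."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.l1 = Linear(d_in, d_hidden, rng)
        self.l2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).silu())

    def parameters(self) -> list[Tensor]:
        return self.l1.parameters() + self.l2.parameters()


class Adam:
    """Adam with the usual bias correction; operates on Tensor parameters."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
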