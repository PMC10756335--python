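"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (tens of parameters tensors, matrices of a
few thousand entries) and trains full-batch on CPU, so a compact tape-based
engine over float64 ndarrays is all that is needed.  :class:`Tensor` wraps an
ndarray, records its parents and a backward closure when gradients are
required, and :meth:`Tensor.backward` walks the tape in reverse topological
order.  Only the operations the drug-response model uses are implemented:
broadcasting arithmetic, matmul, the usual pointwise nonlinearities,
reductions (sum/mean/max), slicing and integer gathering, concatenation, a
3x3 same-padding im2col for the convolutional image encoder, and 2x2 average
pooling.  An :class:`Adam` optimizer (with decoupled-from-nothing classic L2
weight decay added to the gradient, as in the reference Adam) completes the
training loop.

Gradient correctness of each op is covered by central-finite-difference tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "im2col3x3", "avg_pool2", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; molecule loops can make deep graphs
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return _node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return _node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return _node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return _node(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return _node(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError(
                f"matmul expects 2-D operands, got {self.data.shape} @ {other.data.shape}"
            )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return _node(self.data @ other.data, (self, other), bwd)

    # -- pointwise ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return _node(self.data * mask, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return _node(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return _node(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return _node(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return _node(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return _node(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only in the open interval."""
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return _node(np.clip(self.data, lo, hi), (self,), bwd)

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return _node(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes: Sequence[int] | None = None):
        if axes is None:
            axes = tuple(range(self.data.ndim))[::-1]
        inverse = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return _node(self.data.transpose(axes), (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, index):
        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accumulate(acc)

        return _node(self.data[index], (self,), bwd)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        in_shape = self.data.shape

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, in_shape).copy())
                return
            g_exp = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g_exp, in_shape).copy())

        return _node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        elif isinstance(axis, tuple):
            count = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; ties share the gradient equally (deterministic)."""
        max_kd = self.data.max(axis=axis, keepdims=True)
        mask = self.data == max_kd
        counts = mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            if not self.requires_grad:
                return
            g_exp = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(mask * (g_exp / counts))

        out_data = max_kd if keepdims else np.squeeze(max_kd, axis=axis)
        return _node(out_data, (self,), bwd)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def im2col3x3(x: Tensor) -> Tensor:
    """(B, H, W, C) -> (B, H, W, 9*C) patches, 3x3 window, same zero padding.

    Column layout: window offsets in row-major order, channels fastest.
    """
    B, H, W, C = x.data.shape
    padded = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.concatenate(
        [padded[:, i : i + H, j : j + W, :] for i in range(3) for j in range(3)], axis=3
    )

    def bwd(g):
        if not x.requires_grad:
            return
        gp = np.zeros_like(padded)
        for idx, (i, j) in enumerate((i, j) for i in range(3) for j in range(3)):
            gp[:, i : i + H, j : j + W, :] += g[..., idx * C : (idx + 1) * C]
        x._accumulate(gp[:, 1 : 1 + H, 1 : 1 + W, :])

    return _node(cols, (x,), bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2, on (B, H, W, C); H and W must be even."""
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(H, W)}")
    out_data = x.data.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

    def bwd(g):
        if x.requires_grad:
            g_up = np.broadcast_to(
                g[:, :, None, :, None, :] / 4.0, (B, H // 2, 2, W // 2, 2, C)
            ).reshape(B, H, W, C)
            x._accumulate(g_up)

    return _node(out_data, (x,), bwd)


def neighbor_sum(a_hat: np.ndarray, H: Tensor) -> Tensor:
    """Â H with the per-node neighbor contributions summed in sorted order.

    Sorting the contributions by value before summation makes the forward
    pass bit-exactly invariant to any relabeling of the graph's nodes
    (plain matmul is not: BLAS accumulates in label order).  The gradient is
    the ordinary Â^T g.
    """
    a_hat = np.asarray(a_hat, dtype=np.float64)
    H = as_tensor(H)
    contrib = a_hat[:, :, None] * H.data[None, :, :]
    out_data = np.sort(contrib, axis=1).sum(axis=1)

    def bwd(g):
        if H.requires_grad:
            H._accumulate(a_hat.T @ g)

    return _node(out_data, (H,), bwd)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 0.008,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
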