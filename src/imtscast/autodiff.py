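"""Minimal reverse-mode automatic differentiation over numpy arrays.

The forecaster's neural components (meta-filter convolutions, Fourier-analysis
layers, a transformer encoder, graph convolutions) are small enough that a
compact tape-based engine over dense float64 arrays is sufficient on CPU.
The engine supports broadcasting for elementwise ops and batched ``matmul``;
gradients for broadcast operands are reduced back to the operand shape.

Only the operations the model actually uses are implemented.  Every composite
(GELU, softmax, layer norm) is built from these primitives so that a single
set of finite-difference tests covers the whole surface.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "stack",
    "where",
    "gelu",
    "relu",
    "softmax",
    "layer_norm",
    "Adam",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast relative to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_collected")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._collected: list | None = None

    # -- basics ---------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # iterative post-order topological sort over requires_grad nodes
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            node._backward(g)
            assert node._collected is not None
            for p, pg in node._collected:
                if not p.requires_grad:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg
            node._collected = None

    # -- elementwise binary ---------------------------------------------------
    def _binary(self, other, fwd, bwd):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = fwd(self.data, other.data)

        def backward(g: np.ndarray, a=self, b=other):
            ga, gb = bwd(g, a.data, b.data)
            out._collected = [
                (a, _unbroadcast(ga, a.shape)),
                (b, _unbroadcast(gb, b.shape)),
            ]

        out = self._make(data, (self, other), backward)
        return out

    def _unary(self, fwd, bwd):
        data = fwd(self.data)

        def backward(g: np.ndarray, a=self):
            out._collected = [(a, bwd(g, a.data, data))]

        out = self._make(data, (self,), backward)
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        return self._binary(other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide,
                            lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __neg__(self):
        return self._unary(np.negative, lambda g, a, y: -g)

    def __pow__(self, exponent: float):
        e = float(exponent)
        return self._unary(lambda a: a ** e,
                           lambda g, a, y: g * e * a ** (e - 1.0))

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        if a.ndim == 1 and b.ndim == 1:
            return (a * b).sum()
        if a.ndim == 1:
            out = a.reshape(1, -1) @ b
            return out.reshape(out.shape[:-2] + (out.shape[-1],))
        if b.ndim == 1:
            out = a @ b.reshape(-1, 1)
            return out.reshape(out.shape[:-1])
        data = a.data @ b.data

        def backward(g: np.ndarray):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            out._collected = [
                (a, _unbroadcast(ga, a.shape)),
                (b, _unbroadcast(gb, b.shape)),
            ]

        out = self._make(data, (a, b), backward)
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray, a=self):
            if axis is None:
                ga = np.broadcast_to(g, a.shape).copy()
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                ga = np.broadcast_to(g2, a.shape).copy()
            out._collected = [(a, ga)]

        out = self._make(data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = int(np.prod([self.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g: np.ndarray, a=self):
            out._collected = [(a, g.reshape(a.shape))]

        out = self._make(data, (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g: np.ndarray, a=self):
            out._collected = [(a, g.transpose(inv))]

        out = self._make(self.data.transpose(axes), (self,), backward)
        return out

    def swapaxes(self, a1: int, a2: int):
        axes = list(range(self.ndim))
        axes[a1], axes[a2] = axes[a2], axes[a1]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g: np.ndarray, a=self):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            out._collected = [(a, ga)]

        out = self._make(data, (self,), backward)
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        return self._unary(np.exp, lambda g, a, y: g * y)

    def log(self):
        return self._unary(np.log, lambda g, a, y: g / a)

    def sin(self):
        return self._unary(np.sin, lambda g, a, y: g * np.cos(a))

    def cos(self):
        return self._unary(np.cos, lambda g, a, y: -g * np.sin(a))

    def sqrt(self):
        return self._unary(np.sqrt, lambda g, a, y: g * 0.5 / y)

    def erf(self):
        return self._unary(_erf,
                           lambda g, a, y: g * (2.0 / math.sqrt(math.pi))
                           * np.exp(-a * a))


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        parts = np.split(g, splits, axis=axis)
        out._collected = list(zip(ts, parts))

    out = Tensor(data)
    if any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = t if isinstance(t, Tensor) else Tensor(t)
        shape = list(t.shape)
        pos = axis if axis >= 0 else t.ndim + 1 + axis
        shape.insert(pos, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select elementwise by a boolean numpy mask (no gradient through cond)."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    cond = np.asarray(cond, dtype=bool)
    data = np.where(cond, a.data, b.data)

    def backward(g: np.ndarray):
        out._collected = [
            (a, _unbroadcast(np.where(cond, g, 0.0), a.shape)),
            (b, _unbroadcast(np.where(cond, 0.0, g), b.shape)),
        ]

    out = Tensor(data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = backward
    return out


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact GELU x * Phi(x), fused into a single primitive."""
    xd = x.data
    cdf = 0.5 * (1.0 + _erf(xd * (1.0 / _SQRT2)))

    def backward(g: np.ndarray):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * xd * xd)
        out._collected = [(x, g * (cdf + xd * pdf))]

    out = x._make(xd * cdf, (x,), backward)
    return out


def relu(x: Tensor) -> Tensor:
    return where(x.data > 0, x, Tensor(np.zeros(())))


def softmax(x: Tensor, axis: int = -1,
            mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax as a fused primitive.

    ``mask`` is a boolean array broadcastable to ``x`` with True = valid;
    masked positions get weight ~0.  A fully-masked slice yields a uniform
    distribution over its entries (finite, so downstream ``where``
    substitutions never see NaNs).
    """
    logits = x.data
    maskf = None
    if mask is not None:
        maskf = mask.astype(np.float64)
        logits = logits + (maskf - 1.0) * 1e9   # additive -1e9 off-mask
    shift = np.max(logits, axis=axis, keepdims=True)
    e = np.exp(logits - shift)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray):
        gy = g * y
        gx = gy - y * gy.sum(axis=axis, keepdims=True)
        if maskf is not None:
            gx = gx * maskf
        out._collected = [(x, gx)]

    out = x._make(y, (x,), backward)
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gain + bias


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_global_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    ps = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float(np.sum(p.grad * p.grad)) for p in ps))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in ps:
            p.grad *= scale
    return total
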