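"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the graph-attention model: a small tape
of :class:`Tensor` nodes supporting exactly the operations the network needs
(dense algebra, elementwise nonlinearities, row gathering and segment
reductions for message passing / pooling), plus an AdamW optimizer and
global-norm gradient clipping.

All arithmetic is float64. Segment reductions are the only graph-specific
primitives: ``segment_sum`` scatters rows into per-segment totals (used for
attention normalization and message aggregation) and ``segment_max`` routes
gradients to the maximizing rows (ties share the gradient equally, which is
a valid subgradient and deterministic).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_max",
    "AdamW",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data @ other.data,
            _parents=(self, other),
            _backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )
        return out

    def __pow__(self, p: float):
        out = Tensor(
            self.data**p,
            _parents=(self,),
            _backward=lambda g: (g * p * self.data ** (p - 1),),
        )
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask, _parents=(self,), _backward=lambda g: (g * mask,)
        )

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor(
            self.data * factor, _parents=(self,), _backward=lambda g: (g * factor,)
        )

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expm = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(pos, self.data, expm)
        deriv = np.where(pos, 1.0, expm + alpha)
        return Tensor(out_data, _parents=(self,), _backward=lambda g: (g * deriv,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(s, _parents=(self,), _backward=lambda g: (g * s * (1 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor(e, _parents=(self,), _backward=lambda g: (g * e,))

    def log(self):
        return Tensor(
            np.log(self.data), _parents=(self,), _backward=lambda g: (g / self.data,)
        )

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor(r, _parents=(self,), _backward=lambda g: (g * 0.5 / r,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor(
            np.clip(self.data, lo, hi),
            _parents=(self,),
            _backward=lambda g: (g * mask,),
        )

    def dropout(self, p: float, rng: np.random.Generator, train: bool):
        if not train or p <= 0.0:
            return self
        keep = rng.random(self.data.shape) >= p
        scale = keep / (1.0 - p)
        return Tensor(
            self.data * scale, _parents=(self,), _backward=lambda g: (g * scale,)
        )


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate(datas, axis=axis), _parents=tuple(tensors), _backward=backward
    )


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(t.data[idx], _parents=(t,), _backward=backward)


def segment_sum(t: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((n_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, seg, t.data)
    return Tensor(out_data, _parents=(t,), _backward=lambda g: (g[seg],))


def segment_max(t: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.full((n_segments,) + t.data.shape[1:], -np.inf)
    np.maximum.at(out_data, seg, t.data)

    # tie-splitting subgradient: each maximizing row gets grad / n_ties
    is_max = t.data == out_data[seg]
    tie_count = np.zeros_like(out_data)
    np.add.at(tie_count, seg, is_max.astype(np.float64))

    def backward(g):
        return (is_max * (g / tie_count)[seg],)

    return Tensor(out_data, _parents=(t,), _backward=backward)


# --------------------------------------------------------------------- training


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
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
            p.data -= lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most `max_norm`.

    Returns the pre-clip global norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm
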