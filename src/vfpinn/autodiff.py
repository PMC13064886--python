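"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the displacement
network and the physics losses need: elementwise arithmetic, ``sin``/``cos``/
``sigmoid``, generalized ``einsum`` (one or two operands, no ellipsis or
repeated in-operand indices), reductions, reshape/concat/narrow, and ``sqrt``.
Gradients of a scalar output with respect to any participating
:class:`Tensor` are obtained with :meth:`Tensor.backward`.

Every op also accepts plain ndarrays/scalars; if no operand is a ``Tensor``
the result is a plain ndarray, so numerical code written against this module
runs unchanged in a fast no-tape mode (used for inference and for stub field
evaluators in tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "is_tensor", "Adam"]


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()  # tuple of (Tensor, vjp callable)

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents):
        out = Tensor(data)
        parents = tuple((p, fn) for p, fn in parents if p._track())
        out._parents = parents
        out.requires_grad = bool(parents)
        return out

    def _track(self) -> bool:
        return self.requires_grad or bool(self._parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward -----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, vjp in node._parents:
                contrib = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, *shape)


def _coerce(x):
    return x if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def add(a, b):
    if not _any_tensor(a, b):
        return _data(a) + _data(b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data
    return Tensor._make(
        out,
        [
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ],
    )


def mul(a, b):
    if not _any_tensor(a, b):
        return _data(a) * _data(b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data
    return Tensor._make(
        out,
        [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ],
    )


def div(a, b):
    if not _any_tensor(a, b):
        return _data(a) / _data(b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data / b.data
    return Tensor._make(
        out,
        [
            (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * a.data / b.data**2, b.data.shape)),
        ],
    )


def power(a, p: float):
    if not _any_tensor(a):
        return _data(a) ** p
    out = a.data**p
    return Tensor._make(out, [(a, lambda g: g * p * a.data ** (p - 1))])


def sqrt(a):
    return power(a, 0.5)


def sin(a):
    if not _any_tensor(a):
        return np.sin(_data(a))
    return Tensor._make(np.sin(a.data), [(a, lambda g: g * np.cos(a.data))])


def cos(a):
    if not _any_tensor(a):
        return np.cos(_data(a))
    return Tensor._make(np.cos(a.data), [(a, lambda g: -g * np.sin(a.data))])


def sigmoid(a):
    if not _any_tensor(a):
        x = _data(a)
        return 1.0 / (1.0 + np.exp(-x))
    s = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor._make(s, [(a, lambda g: g * s * (1.0 - s))])


def silu(a):
    return mul(a, sigmoid(a))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


_EINSUM_PATHS: dict = {}


def _einsum(spec, *arrays):
    """np.einsum with a memoized contraction path (hot loop helper)."""
    key = (spec, tuple(a.shape for a in arrays))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(spec, *arrays, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(spec, *arrays, optimize=path)


def einsum(spec: str, *ops):
    """``np.einsum`` with reverse-mode support (1 or 2 operands).

    Restrictions (checked implicitly by usage): explicit output spec, no
    ellipsis, no index repeated within a single operand, and every input
    index present in the other operand or the output.
    """
    if not _any_tensor(*ops):
        return _einsum(spec, *(np.asarray(_data(o)) for o in ops))
    lhs, out_spec = spec.split("->")
    in_specs = lhs.split(",")
    tensors = [_as_tensor(o) for o in ops]
    datas = [t.data for t in tensors]
    result = _einsum(spec, *datas)
    parents = []
    if len(tensors) == 1:
        (s,) = in_specs
        back_spec = f"{out_spec}->{s}"
        parents.append((tensors[0], lambda g: _einsum(back_spec, g)))
    elif len(tensors) == 2:
        sa, sb = in_specs
        a, b = tensors

        def vjp_a(g, spec_=f"{out_spec},{sb}->{sa}", other=b.data):
            return _einsum(spec_, g, other)

        def vjp_b(g, spec_=f"{out_spec},{sa}->{sb}", other=a.data):
            return _einsum(spec_, g, other)

        parents.extend([(a, vjp_a), (b, vjp_b)])
    else:  # pragma: no cover
        raise ValueError("einsum supports 1 or 2 operands")
    return Tensor._make(result, parents)


def _swap(x):
    return np.swapaxes(x, -1, -2)


def matmul(a, b):
    """Batched matrix product with numpy broadcasting over leading axes."""
    if not _any_tensor(a, b):
        return _data(a) @ _data(b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def vjp_a(g):
        ad_, bd = a.data, b.data
        if ad_.ndim == 3 and ad_.shape[0] == 1 and g.ndim == 3:
            # shared (unbatched) left operand: contract batch and inner axes
            # in one BLAS call instead of a batched product + reduction
            return np.tensordot(g, bd, axes=([0, 2], [0, 2]))[None]
        return _unbroadcast(g @ _swap(bd), ad_.shape)

    def vjp_b(g):
        return _unbroadcast(_swap(a.data) @ g, b.data.shape)

    return Tensor._make(out, [(a, vjp_a), (b, vjp_b)])


def tsum(a, axis=None):
    if not _any_tensor(a):
        return _data(a).sum(axis=axis)
    out = a.data.sum(axis=axis)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        gg = np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.data.shape).copy()

    return Tensor._make(out, [(a, vjp)])


def tmean(a, axis=None):
    n = _data(a).size if axis is None else _data(a).shape[axis]
    return mul(tsum(a, axis=axis), 1.0 / n)


def reshape(a, *shape):
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    if not _any_tensor(a):
        return _data(a).reshape(shape)
    old = a.data.shape
    return Tensor._make(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def concat(parts, axis=0):
    if not _any_tensor(*parts):
        return np.concatenate([_data(p) for p in parts], axis=axis)
    tensors = [_as_tensor(p) for p in parts]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        n = t.data.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(start, start + n)
        parents.append((t, lambda g, sl=tuple(sl): g[sl]))
        start += n
    return Tensor._make(out, parents)


def narrow(a, start: int, stop: int):
    """Contiguous slice along the first axis."""
    if not _any_tensor(a):
        return _data(a)[start:stop]

    def vjp(g):
        full = np.zeros_like(a.data)
        full[start:stop] = g
        return full

    return Tensor._make(a.data[start:stop], [(a, vjp)])


def value(x) -> np.ndarray:
    """Underlying ndarray of a Tensor or array-like."""
    return _data(x)


class Adam:
    """Standard Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
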