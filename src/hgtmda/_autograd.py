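"""Minimal reverse-mode tensor autodiff engine.

Supports exactly the operations the model needs: broadcasted arithmetic,
matmul, ReLU/sigmoid/exp/log/power, reductions, row-wise softmax and layer
normalisation, integer-array gather, 1-D same-padded convolution, and an
embedding-style ``take``. Gradients are dense float64 arrays; graphs are
built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam", "glorot", "set_grad_enabled"]

_GRAD_ENABLED = True


class set_grad_enabled:
    """Context manager switching graph construction off (inference mode)."""

    def __init__(self, mode: bool):
        self.mode = mode

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = self.mode

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                t._backward = None
                t._parents = ()

    # -- elementwise arithmetic -------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return Tensor._make(out_data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a.grad += -g

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data * b.data

        def bw(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return Tensor._make(out_data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            if a.requires_grad:
                a.grad += g * p * a.data ** (p - 1.0)

        return Tensor._make(out_data, (a,), bw)

    def __matmul__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += a.data.T @ g

        return Tensor._make(out_data, (a, b), bw)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            if a.requires_grad:
                a.grad += g * mask

        return Tensor._make(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            if a.requires_grad:
                a.grad += g * s * (1.0 - s)

        return Tensor._make(s, (a,), bw)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a.grad += g * e

        return Tensor._make(e, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a.grad += g / a.data

        return Tensor._make(np.log(a.data), (a,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp with straight-through gradient inside [lo, hi]."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def bw(g):
            if a.requires_grad:
                a.grad += g * mask

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bw)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if a.requires_grad:
                if axis is None:
                    a.grad += g * np.ones_like(a.data)
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    a.grad += np.broadcast_to(gg, a.data.shape)

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def bw(g):
            if a.requires_grad:
                a.grad += g.reshape(orig)

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    @property
    def T(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a.grad += g.T

        return Tensor._make(a.data.T, (a,), bw)

    def __getitem__(self, idx):
        a = self
        if isinstance(idx, (list, np.ndarray)):
            idx = np.asarray(idx)
        out_data = a.data[idx]

        def bw(g):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return Tensor._make(out_data, (a,), bw)

    # -- composite ops with custom gradients -------------------------------
    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if a.requires_grad:
                a.grad += s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor._make(s, (a,), bw)

    def layer_norm(self, eps: float = 1e-5):
        """Row-wise (last axis) normalisation to zero mean, unit variance."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        var = a.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (a.data - mu) * inv

        def bw(g):
            if a.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gx = (g * xhat).mean(axis=-1, keepdims=True)
                a.grad += inv * (g - gm - xhat * gx)

        return Tensor._make(xhat, (a,), bw)

    def conv1d_same(self, w: "Tensor"):
        """Single-channel 1-D convolution over the last axis, zero-padded.

        self: (n, d) rows convolved independently; w: (K,) odd-length kernel.
        """
        a = self
        k = w.data.shape[0]
        if k % 2 != 1:
            raise ValueError("kernel length must be odd")
        half = k // 2
        n, d = a.data.shape
        xpad = np.pad(a.data, ((0, 0), (half, half)))
        out_data = np.zeros((n, d))
        for t in range(k):
            out_data += w.data[t] * xpad[:, t : t + d]

        def bw(g):
            if a.requires_grad:
                gpad = np.zeros_like(xpad)
                for t in range(k):
                    gpad[:, t : t + d] += w.data[t] * g
                a.grad += gpad[:, half : half + d]
            if w.requires_grad:
                for t in range(k):
                    w.grad[t] += np.sum(g * xpad[:, t : t + d])

        return Tensor._make(out_data, (a, w), bw)

    def take(self, idx: np.ndarray):
        """Embedding lookup: self is a 1-D table, idx an integer array."""
        a = self
        idx = np.asarray(idx)
        out_data = a.data[idx]

        def bw(g):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return Tensor._make(out_data, (a,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor._make(out_data, tuple(tensors), bw)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot-uniform initialised parameter tensor."""
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    shape = (fan_in, fan_out) if shape is None else shape
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Adam:
    """Standard Adam optimiser over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
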