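"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segment transformer needs: broadcasted
arithmetic, batched matmul, softmax / log-softmax, tanh, axis reductions
(sum, mean, max with argmax routing), reshape/transpose/concat, embedding
gather, and element picking.  Gradients are accumulated by topological-order
backward passes; everything is float64 and fully deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._children: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, visited = [], set()

        def build(t: Tensor):
            if id(t) in visited:
                return
            visited.add(id(t))
            for c in t._children:
                build(c)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw():
            if self.requires_grad or self._children:
                self._add_grad(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._children:
                other._add_grad(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw():
            if self.requires_grad or self._children:
                self._add_grad(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._children:
                other._add_grad(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * (other ** -1.0)

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))

        def bw():
            self._add_grad(out.grad * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        # promote 1-D operands so the backward pass only sees matrices
        if self.data.ndim == 1:
            res = self.reshape(1, -1) @ other
            return res.reshape(res.data.shape[:-2] + res.data.shape[-1:])
        if other.data.ndim == 1:
            res = self @ other.reshape(-1, 1)
            return res.reshape(res.data.shape[:-1])
        out = _node(np.matmul(self.data, other.data), (self, other))

        def bw():
            if self.requires_grad or self._children:
                ga = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._add_grad(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._children:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._add_grad(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._add_grad(out.grad.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda: self._add_grad(out.grad.transpose(inv))
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._add_grad(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out = _node(np.max(self.data, axis=axis, keepdims=keepdims), (self,))

        def bw():
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            mask = np.zeros_like(self.data)
            np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)
            self._add_grad(mask * np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out


def _node(data, children) -> Tensor:
    out = Tensor(data)
    out._children = tuple(children)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng=None, scale=None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# -- nonlinear primitives ---------------------------------------------------
def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)
    out = _node(y, (t,))
    out._backward = lambda: t._add_grad(out.grad * (1 - y * y))
    return out


def exp(t: Tensor) -> Tensor:
    y = np.exp(t.data)
    out = _node(y, (t,))
    out._backward = lambda: t._add_grad(out.grad * y)
    return out


def log(t: Tensor) -> Tensor:
    out = _node(np.log(t.data), (t,))
    out._backward = lambda: t._add_grad(out.grad / t.data)
    return out


def gelu(t: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation); smooth activation."""
    c = np.sqrt(2.0 / np.pi)
    inner = tanh((t + t * t * t * 0.044715) * c)
    return t * (inner + 1.0) * 0.5


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (t,))

    def bw():
        g = out.grad
        t._add_grad(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = _node(ls, (t,))

    def bw():
        g = out.grad
        sm = np.exp(ls)
        t._add_grad(g - sm * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t._add_grad(out.grad[tuple(sl)])

    out._backward = bw
    return out


def gather(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out = _node(weight.data[idx], (weight,))

    def bw():
        g = np.zeros_like(weight.data)
        np.add.at(g, idx.reshape(-1), out.grad.reshape(-1, weight.data.shape[-1]))
        weight._add_grad(g)

    out._backward = bw
    return out


def pick(t: Tensor, index: int) -> Tensor:
    """Select one element of a 1-D tensor."""
    out = _node(t.data[index], (t,))

    def bw():
        g = np.zeros_like(t.data)
        g[index] = out.grad
        t._add_grad(g)

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return xc * inv * gamma + beta


class Adam:
    """Adam optimizer over a flat dict of parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
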