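"""Minimal reverse-mode automatic differentiation on numpy arrays.

The hyperbolic network layers need gradients through chains of Möbius
operations and through the unrolled Fréchet-mean fixed-point iteration.
This module provides a small tape-based autodiff engine: a :class:`Tensor`
wrapping an ``ndarray`` plus the primitive operations the geometry and
model code use.  Every dispatching helper (``tanh``, ``asum``, ``clip`` ...)
accepts either a :class:`Tensor` (recorded on the tape) or a plain array
(evaluated eagerly with numpy), so the geometry code has a single
implementation for both training and inference paths.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "is_tensor",
    "value_of",
    "constant",
    "parameter",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "relu",
    "clip",
    "asum",
    "matmul",
    "reshape",
    "take_rows",
    "take2d",
    "softplus",
    "maximum_scalar",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to Tensor.__r<op>__
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
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

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order topological sort (graphs can be very deep)
        topo = []
        state: dict = {}  # id -> 1 in progress, 2 done
        stack = [self]
        while stack:
            node = stack[-1]
            st = state.get(id(node), 0)
            if st == 0:
                state[id(node)] = 1
                for p in node._parents:
                    if p.requires_grad and state.get(id(p), 0) == 0:
                        stack.append(p)
            else:
                stack.pop()
                if st == 1:
                    state[id(node)] = 2
                    topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            # gradients are never mutated in place, so holding a reference is safe
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                self._accum(g)
                other._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            a, b = self.data, other.data
            def bw(g):
                self._accum(g * b)
                other._accum(g * a)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            a, b = self.data, other.data
            def bw(g):
                self._accum(g / b)
                other._accum(-g * a / (b * b))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor._make(self.data ** p, (self,), None)
        if out.requires_grad:
            a = self.data
            out._backward = lambda g: self._accum(g * p * a ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            a, b = self.data, other.data
            def bw(g):
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            out._backward = bw
        return out

    # -- elementwise functions ----------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            a = self.data
            out._backward = lambda g: self._accum(g / a)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(np.where(mask, self.data, 0.0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def clip(self, lo, hi):
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * inside)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            shape = self.data.shape
            def bw(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shape))
            out._backward = bw
        return out

    def reshape(self, shape):
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: self._accum(np.asarray(g).reshape(orig))
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value_of(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the input itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64, copy=True), requires_grad=True)


# -- dispatching helpers (Tensor or ndarray) ---------------------------------

def tanh(x):
    return x.tanh() if is_tensor(x) else np.tanh(x)


def exp(x):
    return x.exp() if is_tensor(x) else np.exp(x)


def log(x):
    return x.log() if is_tensor(x) else np.log(x)


def sqrt(x):
    return x.sqrt() if is_tensor(x) else np.sqrt(x)


def sigmoid(x):
    return x.sigmoid() if is_tensor(x) else expit(x)


def relu(x):
    return x.relu() if is_tensor(x) else np.maximum(x, 0.0)


def clip(x, lo, hi):
    return x.clip(lo, hi) if is_tensor(x) else np.clip(x, lo, hi)


def asum(x, axis=None, keepdims=False):
    if is_tensor(x):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def matmul(a, b):
    if is_tensor(a) or is_tensor(b):
        return _wrap(a) @ _wrap(b)
    return a @ b


def reshape(x, shape):
    return x.reshape(shape) if is_tensor(x) else np.reshape(x, shape)


def maximum_scalar(x, c):
    """max(x, c) elementwise for scalar c (subgradient 0 at the kink)."""
    return relu(x - c) + c


def softplus(x):
    # stable: log1p(exp(-|x|)) + max(x, 0)
    return log(1.0 + exp(-abs_(x))) + relu(x)


def abs_(x):
    if is_tensor(x):
        sign = np.sign(x.data)
        return x * sign
    return np.abs(x)


def take_rows(x, idx):
    """Row gather ``x[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    if not is_tensor(x):
        return x[idx]
    out = Tensor._make(x.data[idx], (x,), None)
    if out.requires_grad:
        shape = x.data.shape
        def bw(g):
            acc = np.zeros(shape)
            np.add.at(acc, idx, np.asarray(g))
            x._accum(acc)
        out._backward = bw
    return out


def take2d(x, rows, cols):
    """Fancy gather ``x[rows, cols]`` (1-D output) with scatter-add backward."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if not is_tensor(x):
        return x[rows, cols]
    out = Tensor._make(x.data[rows, cols], (x,), None)
    if out.requires_grad:
        shape = x.data.shape
        def bw(g):
            acc = np.zeros(shape)
            np.add.at(acc, (rows, cols), np.asarray(g))
            x._accum(acc)
        out._backward = bw
    return out


class Adam:
    """Adam over Euclidean leaf tensors.

    Curvature parameters in the models are softplus-reparameterized, so all
    leaves are unconstrained and the ordinary update applies.
    """

    def __init__(self, params, lr=0.02, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
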