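"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The models in this package are deliberately small (tens of thousands of
parameters), so a compact tape-based autodiff engine in float64 is both fast
enough and fully deterministic.  Only the primitives the encoder and losses
need are provided: broadcast arithmetic, matmul, relu, softmax/log-softmax,
gather / segment-sum (message passing), reductions, sqrt, and smooth-L1.

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar tensor.  Tensors with ``requires_grad=False`` act as constants: values
flow through them but no gradient is stored (used to freeze modules).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # ---- graph plumbing --------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others) -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return  # constants and frozen parameters receive no gradient
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if self._needs(other):
            out.requires_grad = True

            def bwd(g):
                self._accum(g)
                other._accum(g)

            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if self._needs(other):
            out.requires_grad = True

            def bwd(g):
                self._accum(g * other.data)
                other._accum(g * self.data)

            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if self._needs(other):
            out.requires_grad = True

            def bwd(g):
                self._accum(g / other.data)
                other._accum(-g * self.data / other.data**2)

            out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if self._needs(other):
            out.requires_grad = True

            def bwd(g):
                self._accum(g @ other.data.T)
                other._accum(self.data.T @ g)

            out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # ---- nonlinearities & reductions --------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g * 0.5 / np.maximum(val, 1e-300))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if self.requires_grad:
            out.requires_grad = True

            def bwd(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape))

            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        ax = axes if axes else None
        out = Tensor(self.data.transpose(ax), parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            inv = np.argsort(ax) if ax else None
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # ---- indexing / graph ops ---------------------------------------------
    def gather(self, idx: np.ndarray):
        """Row-gather: out[i] = self[idx[i]] (backward scatter-adds)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))
        if self.requires_grad:
            out.requires_grad = True

            def bwd(g):
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

            out._backward = bwd
        return out

    def segment_sum(self, idx: np.ndarray, n: int):
        """out[j] = sum over rows i with idx[i] == j (backward gathers)."""
        idx = np.asarray(idx, dtype=np.intp)
        val = np.zeros((n,) + self.data.shape[1:], dtype=np.float64)
        np.add.at(val, idx, self.data)
        out = Tensor(val, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            out._backward = lambda g: self._accum(g[idx])
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True

            def bwd(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

            out._backward = bwd
        return out

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, parents=(self,))
        if self.requires_grad:
            out.requires_grad = True
            sm = np.exp(ls)

            def bwd(g):
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

            out._backward = bwd
        return out


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def hinge(x: Tensor) -> Tensor:
    """max(0, x)."""
    return x.relu()


def l2_distance(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    """Euclidean distance along the last axis, smoothed at zero for gradients."""
    d = a - b
    return ((d * d).sum(axis=-1) + eps).sqrt()


def smooth_l1(pred: Tensor, target: Tensor, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber with transition `beta`) over all elements."""
    pred = Tensor._wrap(pred)
    target = Tensor._wrap(target)
    diff = pred.data - target.data
    absd = np.abs(diff)
    quad = absd < beta
    val = np.where(quad, 0.5 * diff**2 / beta, absd - 0.5 * beta)
    out = Tensor(val.mean(), parents=(pred, target))
    if pred._needs(target):
        out.requires_grad = True
        dloc = np.where(quad, diff / beta, np.sign(diff)) / diff.size

        def bwd(g):
            pred._accum(g * dloc)
            target._accum(-g * dloc)

        out._backward = bwd
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; `labels` are integer class indices per row."""
    labels = np.asarray(labels, dtype=np.intp)
    ls = logits.log_softmax(axis=-1)
    rows = np.arange(ls.shape[0])
    picked = Tensor(ls.data[rows, labels], parents=(ls,))
    if ls.requires_grad:
        picked.requires_grad = True

        def bwd(g):
            acc = np.zeros_like(ls.data)
            acc[rows, labels] = g
            ls._accum(acc)

        picked._backward = bwd
    return -picked.mean()


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = {k: p for k, p in params.items() if p.requires_grad}
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
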