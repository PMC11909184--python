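"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the hashing network needs: broadcasted
arithmetic, matmul, reductions, tanh/relu/log/exp/sqrt, log-softmax,
2-D convolution (im2col) and max-pooling, plus ``Linear``/``Conv2d`` layers,
an Adam optimizer and a reduce-on-plateau learning-rate scheduler.

All computation is float64 and single-threaded-deterministic: the same
seed, inputs and operation order reproduce gradients bitwise.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A float64 array node in the reverse-mode computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = _parents
        self._backward: Callable[[np.ndarray], None] | None = _backward

    # -- construction helpers ---------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

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

    __float__ = item

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ----------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                      _backward=backward if req else None)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of a scalar (or given seed) into leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # flush any remaining leaves (parents that were themselves leaves)
        for key, g in grads.items():
            for node in topo:
                if id(node) == key:
                    node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data
        def bwd(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))
        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            return ((self, -g),)
        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data
        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))
        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data
        def bwd(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))
        return self._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p
        def bwd(g):
            return ((self, g * p * self.data ** (p - 1)),)
        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data
        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape)))
        return self._make(out_data, (self, other), bwd)

    # -- reductions and reshapes -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)
        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape
        def bwd(g):
            return ((self, g.reshape(orig)),)
        return self._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        axes = axes or None
        out_data = self.data.transpose(axes)
        def bwd(g):
            inv = np.argsort(axes) if axes else None
            return ((self, g.transpose(inv)),)
        return self._make(out_data, (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)
        return self._make(out_data, (self,), bwd)

    # -- elementwise nonlinearities ----------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)
        def bwd(g):
            return ((self, g * (1.0 - out_data ** 2)),)
        return self._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        def bwd(g):
            return ((self, g * (self.data > 0.0)),)
        return self._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)
        def bwd(g):
            return ((self, g / self.data),)
        return self._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)
        def bwd(g):
            return ((self, g * out_data),)
        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def bwd(g):
            return ((self, g * 0.5 / out_data),)
        return self._make(out_data, (self,), bwd)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))
    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  _parents=tuple(tensors) if req else (),
                  _backward=bwd if req else None)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along `axis`."""
    m = np.max(x.data, axis=axis, keepdims=True)  # constant shift
    shifted = x - m
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


# ---------------------------------------------------------------------------
# Convolution / pooling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, kh, kw, oh, ow) strided patch view (copy)."""
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (OC, C, kh, kw); ``b`` shape (OC,).
    """
    n, c, h, wdt = x.data.shape
    oc, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wdt + 2 * padding - kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("convolution output would be empty; check sizes")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride, oh, ow).reshape(n, c * kh * kw, oh * ow)
    wflat = w.data.reshape(oc, c * kh * kw)
    out_data = (wflat[None] @ cols).reshape(n, oc, oh, ow) + b.data[None, :, None, None]

    def bwd(g):
        gflat = g.reshape(n, oc, oh * ow)
        gw = np.einsum("nop,nkp->ok", gflat, cols).reshape(w.data.shape)
        gb = gflat.sum(axis=(0, 2))
        gcols = (wflat.T[None] @ gflat).reshape(n, c, kh, kw, oh, ow)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += gcols[:, :, i, j]
        if padding:
            gx = gxp[:, :, padding:padding + h, padding:padding + wdt]
        else:
            gx = gxp
        return ((x, gx), (w, gw), (b, gb))

    req = x.requires_grad or w.requires_grad or b.requires_grad
    return Tensor(out_data, requires_grad=req,
                  _parents=(x, w, b) if req else (),
                  _backward=bwd if req else None)


def max_pool2d(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Max pooling, NCHW layout; overlapping windows supported."""
    n, c, h, w = x.data.shape
    oh = (h - kernel) // stride + 1
    ow = (w - kernel) // stride + 1
    cols = _im2col(x.data, kernel, kernel, stride, oh, ow)
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bwd(g):
        gx = np.zeros_like(x.data)
        for k in range(kernel * kernel):
            i, j = divmod(k, kernel)
            mask = (arg == k)
            if not mask.any():
                continue
            contrib = g * mask
            gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += contrib
        return ((x, gx),)

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, _parents=(x,) if req else (),
                  _backward=bwd if req else None)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks parameters through attribute discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Affine map with fan-in uniform initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(out_features,)),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator):
        fan_in = in_channels * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(out_channels,)),
                           requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment estimation with the conventional defaults."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply the learning rate by `factor` after `patience` epochs without
    improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, patience: int = 10, factor: float = 0.1,
                 min_lr: float = 1e-8):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
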