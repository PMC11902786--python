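"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the spectral networks in this package
need: broadcasted arithmetic, (batched) matmul, pointwise nonlinearities,
reductions, shape manipulation, batch/layer normalization, a fused
softmax cross-entropy, and the selective-scan recurrence (which registers
a hand-written backward pass so the graph stays small).

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on
a scalar. The engine is dtype-preserving: float32 graphs stay float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "cross_entropy", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev if self.requires_grad else ()
        self._backward = None

    # ---- plumbing -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # ---- pointwise ------------------------------------------------------

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (0.5 / y))

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def silu(self):
        """x * sigmoid(x) — the gating activation inside the Mamba block."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        out._backward = _bw
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x))
        y = np.logaddexp(np.zeros((), dtype=self.data.dtype), self.data)
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * s)

        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope).astype(self.data.dtype))

        out._backward = _bw
        return out

    # ---- reductions / shape ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        out._backward = _bw
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis).copy(), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                items = idx if isinstance(idx, tuple) else (idx,)
                if all(isinstance(i, (slice, int)) for i in items):
                    full[idx] += g  # basic slices cannot alias; += is exact
                else:
                    np.add.at(full, idx, g)
                self._accum(full)

        out._backward = _bw
        return out

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad one axis (used for causal convolution)."""
        width = [(0, 0)] * self.data.ndim
        width[axis] = (before, after)
        out = Tensor(np.pad(self.data, width), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                sl = [slice(None)] * self.data.ndim
                sl[axis] = slice(before, before + self.data.shape[axis])
                self._accum(g[tuple(sl)])

        out._backward = _bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = _bw
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under `logits` [B, C]."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = labels.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(np.asarray(loss, dtype=logits.dtype), _prev=(logits,))

    def _bw(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum((g / n) * p)

    out._backward = _bw
    return out


class Adam:
    """Adam with the conventional defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
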