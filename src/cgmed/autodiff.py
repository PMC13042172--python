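"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the causally-constrained autoencoder: dense and
1-D convolutional layers, max pooling, elementwise nonlinearities,
reductions, concatenation, matrix inverse (for the differentiable
least-squares residuals inside the penalties), and AdamW / RMSprop
optimizers with global-norm gradient clipping.  Everything is float64 and
single-threaded, which keeps training deterministic for a fixed seed.

Gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv1d", "maxpool1d", "matmul",
           "relu", "tanh", "inv", "AdamW", "RMSprop", "clip_global_norm"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph mechanics -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._prev:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(g, self.data.shape)

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            self._accum(out.grad)
            other._accum(out.grad)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data ** 2)
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda: self._accum(out.grad.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)
        out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum grad over broadcast dimensions back to `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# free-function ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def bw():
        a._accum(out.grad @ b.data.T)
        b._accum(a.data.T @ out.grad)
    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))
    out._backward = lambda: x._accum(out.grad * (x.data > 0))
    return out


def tanh(x: Tensor) -> Tensor:
    out = Tensor(np.tanh(x.data), _prev=(x,))
    out._backward = lambda: x._accum(out.grad * (1 - out.data ** 2))
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(idx)])
    out._backward = bw
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, L) padded same -> (N, L, C*k) sliding windows."""
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, k - 1 - pad)))
    n, c, lp = xp.shape
    l_out = lp - k + 1
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, l_out, k), strides=(s0, s1, s2, s2))
    return cols.transpose(0, 2, 1, 3).reshape(n, l_out, c * k)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution.  x: (N, C, L); w: (F, C, K); b: (F,)."""
    n, c, l = x.data.shape
    f, c_w, k = w.data.shape
    if c != c_w:
        raise ValueError(f"conv1d expected {c_w} input channels, got {c}")
    cols = _im2col(x.data, k)                       # (N, L, C*K)
    wm = w.data.reshape(f, c * k)                   # (F, C*K)
    out_data = cols @ wm.T + b.data                 # (N, L, F)
    out = Tensor(out_data.transpose(0, 2, 1), _prev=(x, w, b))   # (N, F, L)

    def bw():
        g = out.grad.transpose(0, 2, 1)             # (N, L, F)
        b._accum(g.sum(axis=(0, 1)))
        w._accum((g.reshape(-1, f).T @ cols.reshape(-1, c * k)).reshape(f, c, k))
        gcols = g @ wm                               # (N, L, C*K)
        gx = np.zeros_like(x.data)
        pad = (k - 1) // 2
        gxp = np.pad(gx, ((0, 0), (0, 0), (pad, k - 1 - pad)))
        gcols4 = gcols.reshape(n, l, c, k).transpose(0, 2, 1, 3)  # (N,C,L,K)
        for j in range(k):
            gxp[:, :, j:j + l] += gcols4[:, :, :, j]
        x._accum(gxp[:, :, pad:pad + l])
    out._backward = bw
    return out


def maxpool1d(x: Tensor, size: int = 2, stride: int = 2) -> Tensor:
    n, c, l = x.data.shape
    l_out = (l - size) // stride + 1
    windows = np.stack([x.data[:, :, i * stride:i * stride + size]
                        for i in range(l_out)], axis=2)   # (N, C, L_out, size)
    arg = windows.argmax(axis=3)
    out = Tensor(windows.max(axis=3), _prev=(x,))

    def bw():
        gx = np.zeros_like(x.data)
        for i in range(l_out):
            sel = arg[:, :, i]
            idx_n, idx_c = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            gx[idx_n, idx_c, i * stride + sel] += out.grad[:, :, i]
        x._accum(gx)
    out._backward = bw
    return out


def inv(a: Tensor) -> Tensor:
    """Matrix inverse with the standard adjoint  dA^-1 = -A^-1 dA A^-1."""
    inv_data = np.linalg.inv(a.data)
    out = Tensor(inv_data, _prev=(a,))
    out._backward = lambda: a._accum(-inv_data.T @ out.grad @ inv_data.T)
    return out


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def clip_global_norm(params, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-5):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mh / (np.sqrt(vh) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class RMSprop:
    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8, weight_decay=1e-5):
        self.params = list(params)
        self.lr, self.alpha, self.eps, self.wd = lr, alpha, eps, weight_decay
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.alpha
            s += (1 - self.alpha) * p.grad ** 2
            p.data -= self.lr * (p.grad / (np.sqrt(s) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
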