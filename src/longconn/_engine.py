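"""Minimal reverse-mode automatic differentiation on numpy arrays.

Float64 throughout. The graph is built eagerly by the op functions below and
consumed once by :meth:`Tensor.backward`; no tapes persist across calls.
Only the operations the package's networks need are provided — dense affine
maps, 1D convolution/pooling, the sigmoid/tanh/relu nonlinearities,
concatenation, dropout, and a numerically stable binary cross-entropy on
logits.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "conv1d",
    "maxpool1d",
    "concat",
    "mean_last",
    "dropout",
    "bce_with_logits",
    "Adam",
]


class Tensor:
    """A node in the computation graph: a value, its gradient, a backward rule."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.requires_grad = bool(requires_grad)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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

    def zero_grad(self):
        self.grad = None


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    # collapse broadcast axes back to the parent's shape
    extra = g.ndim - t.data.ndim
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    for ax, n in enumerate(t.data.shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    t.grad = g if t.grad is None else t.grad + g


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def bw(g):
        _accum(a, g)
        _accum(b, g)

    return _node(data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _node(data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _node(data, (a, b), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def bw(g):
        _accum(x, g * s * (1.0 - s))

    return _node(s, (x,), bw)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def bw(g):
        _accum(x, g * (1.0 - t * t))

    return _node(t, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def bw(g):
        _accum(x, g * mask)

    return _node(data, (x,), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-length 1D convolution (cross-correlation), stride 1, zero padding.

    x: (N, C_in, L); w: (C_out, C_in, K) with K odd; b: (C_out,).
    """
    n, c_in, length = x.data.shape
    c_out, c_in_w, k = w.data.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input {c_in}, weight {c_in_w}")
    if k % 2 != 1:
        raise ValueError("kernel size must be odd for same-length convolution")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # im2col: windows (N, C_in, L, K) -> (N*L, C_in*K), one matmul per pass
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * length, c_in * k)
    wm = w.data.reshape(c_out, c_in * k)
    data = (col @ wm.T).reshape(n, length, c_out).transpose(0, 2, 1)
    data = data + b.data[None, :, None]

    def bw(g):
        _accum(b, g.sum(axis=(0, 2)))
        gt = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * length, c_out)
        _accum(w, (gt.T @ col).reshape(c_out, c_in, k))
        gcol = (gt @ wm).reshape(n, length, c_in, k).transpose(0, 2, 1, 3)
        gxp = np.zeros_like(xp)
        for kk in range(k):  # col2im scatter
            gxp[:, :, kk:kk + length] += gcol[:, :, :, kk]
        _accum(x, gxp[:, :, pad:pad + length] if pad else gxp)

    return _node(data, (x, w, b), bw)


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling; a trailing remainder of < k frames is dropped."""
    n, c, length = x.data.shape
    if k == 1:
        return _node(x.data, (x,), lambda g: _accum(x, g))
    out_len = length // k
    xv = x.data[:, :, : out_len * k].reshape(n, c, out_len, k)
    data = xv.max(axis=3)

    def bw(g):
        # route gradient to the first maximal entry of each window
        hit = xv == data[..., None]
        first = hit & (np.cumsum(hit, axis=3) == 1)
        full = np.zeros_like(x.data)
        full[:, :, : out_len * k] = (first * g[..., None]).reshape(n, c, out_len * k)
        _accum(x, full)

    return _node(data, (x,), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _node(data, tuple(tensors), bw)


def mean_last(x: Tensor) -> Tensor:
    """Mean over the last axis (global average pooling over signal length)."""
    length = x.data.shape[-1]
    data = x.data.mean(axis=-1)

    def bw(g):
        _accum(x, np.repeat(g[..., None], length, axis=-1) / length)

    return _node(data, (x,), bw)


def reshape(x: Tensor, shape) -> Tensor:
    data = x.data.reshape(shape)

    def bw(g):
        _accum(x, g.reshape(x.data.shape))

    return _node(data, (x,), bw)


def take_step(x: Tensor, s: int) -> Tensor:
    """Select step s along axis 1 of a (N, S, F) tensor -> (N, F)."""
    data = x.data[:, s]

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, s] = g
        _accum(x, full)

    return _node(data, (x,), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only during training."""
    if rate <= 0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    data = x.data * mask

    def bw(g):
        _accum(x, g * mask)

    return _node(data, (x,), bw)


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of logits z against 0/1 targets y.

    Uses the log-sum-exp form max(z,0) − z·y + log(1+exp(−|z|)), stable for
    large |z|; the gradient is (σ(z) − y)/n.
    """
    y = np.asarray(y, dtype=np.float64)
    zd = z.data
    loss = np.maximum(zd, 0.0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    data = np.array(loss.mean())
    n = zd.size

    def bw(g):
        s = np.empty_like(zd)
        pos = zd >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-zd[pos]))
        e = np.exp(zd[~pos])
        s[~pos] = e / (1.0 + e)
        _accum(z, g * (s - y) / n)

    return _node(data, (z,), bw)


class Adam:
    """Adam optimiser with optional decoupled weight decay (AdamW form)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
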