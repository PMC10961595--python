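"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the recognizer needs: broadcasting
arithmetic, matmul, the usual nonlinearities, log-sum-exp / log-softmax,
gathers (for CTC state transitions and per-sample time reversal), and a
strided/dilated 1-D convolution. Gradients are accumulated by topological
sweep over the tape; everything is float64 unless the caller says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "logsumexp",
    "log_softmax",
    "where",
    "gather_last",
    "gather_time",
    "conv1d",
    "Adam",
    "clip_global_norm",
]

NEG_INF = -1.0e30  # guarded -inf: keeps logsumexp gradients finite


def _as_array(x, dtype=np.float64):
    if isinstance(x, np.ndarray):
        return x.astype(dtype, copy=False)
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    def __getitem__(self, key):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        return Tensor._make(a.data[key], (a,), bwd)

    # -- elementwise ----------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def sigmoid(self):
        a = self
        out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def bwd(g):
            a._accum(g * out * (1.0 - out))

        return Tensor._make(out, (a,), bwd)

    def tanh(self):
        a = self
        out = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out * out))

        return Tensor._make(out, (a,), bwd)

    def exp(self):
        a = self
        out = np.exp(np.clip(a.data, NEG_INF, 60))

        def bwd(g):
            a._accum(g * out)

        return Tensor._make(out, (a,), bwd)

    def reciprocal(self):
        a = self
        out = 1.0 / a.data

        def bwd(g):
            a._accum(-g * out * out)

        return Tensor._make(out, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def bwd(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)


# -- free functions ------------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def stack(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def logsumexp(x: Tensor, axis=-1, keepdims=False):
    a = x
    m = np.max(a.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out = m + np.log(s)
    soft = e / s

    def bwd(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        a._accum(gg * soft)

    res = out if keepdims else np.squeeze(out, axis=axis)
    return Tensor._make(res, (a,), bwd)


def log_softmax(x: Tensor, axis=-1):
    a = x
    m = np.max(a.data, axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    soft = np.exp(out)

    def bwd(g):
        a._accum(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out, (a,), bwd)


def where(cond: np.ndarray, a, b):
    """Elementwise select; `cond` is a constant boolean array."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.shape))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), bwd)


def gather_last(x: Tensor, idx: np.ndarray):
    """y[..., j] = x[..., idx[..., j]] with integer `idx` broadcast over x's
    leading axes; used to pick per-state emission log-probabilities."""
    a = x
    idx = np.asarray(idx, dtype=np.intp)
    idxb = np.broadcast_to(idx, x.shape[:-1] + idx.shape[-1:])
    out = np.take_along_axis(a.data, idxb, axis=-1)

    def bwd(g):
        full = np.zeros_like(a.data)
        grids = np.meshgrid(*[np.arange(s) for s in idxb.shape[:-1]], indexing="ij")
        lead = tuple(gr[..., None] for gr in grids)
        np.add.at(full, lead + (idxb,), g)
        a._accum(full)

    return Tensor._make(out, (a,), bwd)


def gather_time(x: Tensor, idx: np.ndarray):
    """y[b, t] = x[b, idx[b, t]] for x of shape [B, T, ...]; used to reverse
    each sequence within its own valid length."""
    a = x
    idx = np.asarray(idx, dtype=np.intp)
    B = x.shape[0]
    bi = np.arange(B)[:, None]
    out = a.data[bi, idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, (bi, idx), g)
        a._accum(full)

    return Tensor._make(out, (a,), bwd)


def _conv_geometry(T: int, K: int, stride: int, dilation: int, padding: str):
    extent = (K - 1) * dilation + 1
    if padding == "same":
        out = -(-T // stride)
        total = max(0, (out - 1) * stride + extent - T)
        left, right = total // 2, total - total // 2
    elif padding == "causal":
        left, right = extent - 1, 0
        out = (T + left + right - extent) // stride + 1
    elif padding == "valid":
        left = right = 0
        out = (T - extent) // stride + 1
    else:  # pragma: no cover - guarded by layer constructors
        raise ValueError(f"unknown padding {padding!r}")
    return out, left, right, extent


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, dilation: int = 1,
           padding: str = "same"):
    """1-D convolution, x:[B,C,T], w:[F,C,K], b:[F] -> [B,F,T_out]."""
    B, C, T = x.shape
    F, Cw, K = w.shape
    if Cw != C:
        raise ValueError(f"conv1d channel mismatch: input {C}, kernel {Cw}")
    out_len, left, right, extent = _conv_geometry(T, K, stride, dilation, padding)
    if out_len < 1:
        raise ValueError(f"conv1d: input length {T} too short for kernel extent {extent}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right)))
    win = np.lib.stride_tricks.sliding_window_view(xp, extent, axis=2)
    win = win[:, :, ::stride, ::dilation]            # [B, C, out, K]
    patches = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, out_len, C * K)
    w2 = w.data.reshape(F, C * K)
    y = patches @ w2.T + b.data[None, None, :]       # [B, out, F]
    y = np.ascontiguousarray(y.transpose(0, 2, 1))   # [B, F, out]

    def bwd(g):
        gy = np.ascontiguousarray(g.transpose(0, 2, 1))          # [B, out, F]
        if b.requires_grad:
            b._accum(gy.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = gy.reshape(-1, F).T @ patches.reshape(-1, C * K)
            w._accum(gw.reshape(F, C, K))
        if x.requires_grad:
            gcols = (gy @ w2).reshape(B, out_len, C, K)          # [B, out, C, K]
            gxp = np.zeros_like(xp)
            pos0 = np.arange(out_len) * stride
            for k in range(K):
                gxp[:, :, pos0 + k * dilation] += gcols[:, :, :, k].transpose(0, 2, 1)
            end = gxp.shape[2] - right
            x._accum(gxp[:, :, left:end])

    return Tensor._make(y, (x, w, b), bwd)


# -- optimisation --------------------------------------------------------------

class Adam:
    """Adam with the usual bias correction (Kingma & Ba defaults)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

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
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def clip_global_norm(params, max_norm: float) -> float:
    """Rescale all gradients so their joint L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = total ** 0.5
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
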