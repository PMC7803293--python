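"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The segmentation network needs only a small, fixed set of differentiable
operations: 2-D (dilated) convolution, 2x2 transposed convolution, 2x2
max/average pooling, global and per-pixel channel pooling, sigmoid/ReLU,
broadcast arithmetic and channel concatenation.  Rather than depend on a
deep-learning framework, this module implements exactly that set on top of
NumPy, using im2col + BLAS matmul for the convolutions.

Tensors carry NCHW-ordered float64/float32 arrays.  Gradients are
accumulated by a topological-order sweep from the loss.  Everything is
deterministic: there is no dropout, no atomics, no threading beyond BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "avg_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "channel_mean",
    "channel_max",
    "sigmoid",
    "relu",
    "concat",
    "bce_loss",
    "Adam",
]


class Tensor:
    """Node in the computation graph.

    Parameters
    ----------
    data:
        The value, any-dimensional ``ndarray`` (network code uses NCHW).
    parents:
        Tensors this node was computed from.
    backward_fn:
        Callable ``grad_out -> tuple_of_parent_grads`` (``None`` entries for
        parents that need no gradient).
    requires_grad:
        Leaf flag; non-leaf nodes require grad iff any parent does.
    """

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad", "name")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node (typically a scalar loss)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires scalar output")
            grad = np.ones_like(self.data)
        order = []
        seen = set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            order.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None or not node.requires_grad:
                continue
            if node.requires_grad and node.backward_fn is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node.backward_fn(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- convenience arithmetic -----------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), constant(-1.0)))

    def __neg__(self):
        return mul(self, constant(-1.0))


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x):
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x, name=""):
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True, name=name)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bwd(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out, (a, b), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g):
        return (g * s * (1.0 - s),)

    return Tensor(s, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0.0)

    def bwd(g):
        return (g * mask,)

    return Tensor(out, (x,), bwd)


def concat(tensors, axis=1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tensors, bwd)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Return (N*H*W, C*k*k) patch matrix for 'same' dilated convolution.

    Padding is K//2 with K = k + (k-1)(dilation-1), so output spatial size
    equals input spatial size (k odd).
    """
    n, c, h, w = x.shape
    K = k + (k - 1) * (dilation - 1)
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (K, K), axis=(2, 3))  # N,C,H,W,K,K
    win = win[..., ::dilation, ::dilation]              # N,C,H,W,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same'-padded 2-D correlation.

    ``x``: (N, C, H, W); ``w``: (O, C, k, k) with odd k; ``b``: (O,) or None.
    ``dilation`` spaces kernel taps ``dilation`` pixels apart, giving an
    effective kernel side of k + (k-1)(dilation-1) without extra weights.
    """
    n, c, h, wd = x.data.shape
    o, cw, k, k2 = w.data.shape
    if k != k2 or k % 2 != 1:
        raise ValueError("kernel must be square with odd side")
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cw}")
    cols = _im2col(x.data, k, dilation)
    wmat = w.data.reshape(o, c * k * k)
    out = cols @ wmat.T                     # (N*H*W, O)
    out = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
        gw = (gmat.T @ cols).reshape(o, c, k, k) if w.requires_grad else None
        gx = None
        if x.requires_grad:
            # transpose of same-padded correlation = same-padded correlation
            # with the spatially flipped, io-swapped kernel
            wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, k, k)
            gcols = _im2col(g, k, dilation)
            gx = (gcols @ wt.reshape(c, o * k * k).T)
            gx = gx.reshape(n, h, wd, c).transpose(0, 3, 1, 2)
        gb = g.sum(axis=(0, 2, 3)) if (b is not None and b.requires_grad) else None
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor(out, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x upsampling transposed convolution, kernel 2x2, stride 2.

    ``x``: (N, C, H, W) -> (N, O, 2H, 2W); ``w``: (C, O, 2, 2).
    Stride equal to kernel size means output blocks do not overlap, so the
    operation is an einsum followed by a block interleave.
    """
    n, c, h, wd = x.data.shape
    cw, o, k1, k2 = w.data.shape
    if (k1, k2) != (2, 2):
        raise ValueError("only 2x2 kernels supported")
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cw}")
    # (N,H,W,O,2,2)
    y = np.einsum("nchw,coij->nhwoij", x.data, w.data, optimize=True)
    out = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gblk = g.reshape(n, o, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,O,2,2
        gx = np.einsum("nhwoij,coij->nchw", gblk, w.data, optimize=True) \
            if x.requires_grad else None
        gw = np.einsum("nhwoij,nchw->coij", gblk, x.data, optimize=True) \
            if w.requires_grad else None
        gb = g.sum(axis=(0, 2, 3)) if (b is not None and b.requires_grad) else None
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor(out, parents, bwd)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dims")
    blk = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = blk.max(axis=(3, 5))

    def bwd(g):
        # ties split the gradient equally (deterministic, symmetric)
        mask = (blk == out[:, :, :, None, :, None]).astype(np.float64)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * g[:, :, :, None, :, None]
        return (gx.reshape(n, c, h, w),)

    return Tensor(out, (x,), bwd)


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    """factor x factor average pooling, stride = factor."""
    n, c, h, w = x.data.shape
    f = factor
    if h % f or w % f:
        raise ValueError("avg_pool2d requires divisible spatial dims")
    blk = x.data.reshape(n, c, h // f, f, w // f, f)
    out = blk.mean(axis=(3, 5))

    def bwd(g):
        gx = np.broadcast_to(g[:, :, :, None, :, None] / (f * f),
                             (n, c, h // f, f, w // f, f))
        return (gx.reshape(n, c, h, w),)

    return Tensor(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1), mean over the spatial extent."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def bwd(g):
        return (np.broadcast_to(g / (h * w), x.data.shape).copy(),)

    return Tensor(out, (x,), bwd)


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1), max over the spatial extent."""
    out = x.data.max(axis=(2, 3), keepdims=True)

    def bwd(g):
        mask = (x.data == out).astype(np.float64)
        mask /= mask.sum(axis=(2, 3), keepdims=True)
        return (mask * g,)

    return Tensor(out, (x,), bwd)


def channel_mean(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W), per-pixel mean over channels."""
    c = x.data.shape[1]
    out = x.data.mean(axis=1, keepdims=True)

    def bwd(g):
        return (np.broadcast_to(g / c, x.data.shape).copy(),)

    return Tensor(out, (x,), bwd)


def channel_max(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W), per-pixel max over channels."""
    out = x.data.max(axis=1, keepdims=True)

    def bwd(g):
        mask = (x.data == out).astype(np.float64)
        mask /= mask.sum(axis=1, keepdims=True)
        return (mask * g,)

    return Tensor(out, (x,), bwd)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(yhat: Tensor, y: np.ndarray, clip: float = 1e-7) -> Tensor:
    """Binary cross-entropy: sum over pixels, mean over batch elements.

    ``yhat`` holds probabilities in [0,1]; values are clipped to
    [clip, 1-clip] before the logarithm.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != yhat.data.shape:
        raise ValueError(f"shape mismatch: labels {y.shape}, probs {yhat.data.shape}")
    batch = yhat.data.shape[0] if yhat.data.ndim >= 1 else 1
    p = np.clip(yhat.data, clip, 1.0 - clip)
    loss = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum() / batch

    def bwd(g):
        inside = (yhat.data > clip) & (yhat.data < 1.0 - clip)
        gy = np.where(inside, (p - y) / (p * (1.0 - p)), 0.0) / batch
        return (g * gy,)

    return Tensor(np.float64(loss), (yhat,), bwd)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer over a dict of leaf Tensors."""

    def __init__(self, params: dict, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = float(beta1), float(beta2), float(eps)
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
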