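"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small enough to train on a CPU,
so rather than depending on a full deep-learning framework the package ships
a compact autodiff engine that supports exactly the operations the network
needs: broadcast arithmetic, matrix products, valid (optionally dilated)
convolution, gather-based padding/resampling, slicing, elementwise max,
reductions, the usual pointwise nonlinearities, concatenation and the
zero-stuffing upsampling used by transpose convolution.

Gradients are accumulated by a topological sweep over the recorded graph.
Float32 is the working precision for network tensors; float64 inputs are
kept in float64 (useful for numerical gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "log",
    "power",
    "tsum",
    "tmean",
    "amax",
    "maximum",
    "concat",
    "reshape",
    "getitem",
    "gather2d",
    "pad_zero2d",
    "conv2d",
    "dilate2",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_own")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self._grad_own = False

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        self._grad_own = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the closure so intermediate buffers can be reclaimed
                node._backward = None
                node._parents = ()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    """Add ``g`` into ``t.grad`` without copying fresh arrays.

    The first contribution is stored by reference; only when a second
    contribution arrives is a new array allocated (the stored reference may
    alias an upstream gradient, so it is never mutated in place).
    """
    if not t.requires_grad and t._backward is None:
        return
    if t.grad is None:
        t.grad = g
        t._grad_own = False
    elif t._grad_own:
        t.grad += g
    else:
        t.grad = t.grad + g
        t._grad_own = True


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None or t._parents for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        _accumulate(a, g * exponent * a.data ** (exponent - 1.0))

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0)

    def backward(g):
        _accumulate(a, g * (a.data > 0))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    data = np.empty_like(a.data)
    pos = a.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    data[~pos] = ez / (1.0 + ez)

    def backward(g):
        _accumulate(a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def log(a: Tensor, eps: float = 1e-7) -> Tensor:
    a = as_tensor(a)
    clipped = np.clip(a.data, eps, None)
    data = np.log(clipped)

    def backward(g):
        _accumulate(a, g / clipped)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions and elementwise max
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        _accumulate(a, np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def amax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        expanded = data if keepdims else np.expand_dims(data, axis)
        mask = (a.data == expanded)
        counts = mask.sum(axis=axis, keepdims=True)
        gexp = g if keepdims else np.expand_dims(g, axis)
        _accumulate(a, mask * (gexp / counts))

    return _make(data, (a,), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties route their gradient to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    data = np.where(take_a, a.data, b.data)

    def backward(g):
        _accumulate(a, _unbroadcast(g * take_a, a.data.shape))
        _accumulate(b, _unbroadcast(g * (~take_a), b.data.shape))

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        _accumulate(a, g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def getitem(a: Tensor, key) -> Tensor:
    a = as_tensor(a)
    data = a.data[key]

    def backward(g):
        full = np.zeros_like(a.data)
        full[key] += g
        _accumulate(a, full)

    return _make(data, (a,), backward)


def gather2d(a: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """Index the two trailing (spatial) axes with integer maps.

    Implements reflect/edge padding and nearest-neighbour resampling for
    (batch, channel, H, W) tensors; the backward pass scatter-adds.
    """
    a = as_tensor(a)
    iy = np.asarray(iy, dtype=np.intp)
    ix = np.asarray(ix, dtype=np.intp)
    data = a.data[:, :, iy[:, None], ix[None, :]]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, (slice(None), slice(None), iy[:, None], ix[None, :]), g)
        _accumulate(a, full)

    return _make(data, (a,), backward)


def pad_zero2d(a: Tensor, lo_h: int, hi_h: int, lo_w: int, hi_w: int) -> Tensor:
    a = as_tensor(a)
    data = np.pad(a.data, ((0, 0), (0, 0), (lo_h, hi_h), (lo_w, hi_w)))

    def backward(g):
        H, W = a.data.shape[2:]
        _accumulate(a, g[:, :, lo_h:lo_h + H, lo_w:lo_w + W])

    return _make(data, (a,), backward)


def dilate2(a: Tensor) -> Tensor:
    """Insert zeros between pixels (stride-2 zero stuffing): H -> 2H-1."""
    a = as_tensor(a)
    B, C, H, W = a.data.shape
    data = np.zeros((B, C, 2 * H - 1, 2 * W - 1), dtype=a.data.dtype)
    data[:, :, ::2, ::2] = a.data

    def backward(g):
        _accumulate(a, g[:, :, ::2, ::2])

    return _make(data, (a,), backward)


def sep_correlate_valid(x: Tensor, row: np.ndarray) -> Tensor:
    """Valid correlation of a pre-padded map with the separable kernel
    ``outer(row, row)``, applied per channel (used by all blur filters)."""
    x = as_tensor(x)
    row = np.asarray(row, dtype=x.dtype)
    k = row.size
    Hp, Wp = x.data.shape[-2:]
    H, W = Hp - k + 1, Wp - k + 1
    if H < 1 or W < 1:
        raise ValueError("input smaller than the kernel support")
    tmp = np.zeros(x.data.shape[:-2] + (H, Wp), dtype=x.dtype)
    for i in range(k):
        tmp += row[i] * x.data[..., i:i + H, :]
    out = np.zeros(x.data.shape[:-2] + (H, W), dtype=x.dtype)
    for j in range(k):
        out += row[j] * tmp[..., :, j:j + W]
    del tmp

    def backward(g):
        gtmp = np.zeros(x.data.shape[:-2] + (H, Wp), dtype=g.dtype)
        for j in range(k):
            gtmp[..., :, j:j + W] += row[j] * g
        gx = np.zeros_like(x.data)
        for i in range(k):
            gx[..., i:i + H, :] += row[i] * gtmp
        _accumulate(x, gx)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Valid cross-correlation of a pre-padded (B,Cin,H,W) map with (Co,Cin,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    B, Ci, H, W = xd.shape
    Co, Ciw, kh, kw = wd.shape
    if Ci != Ciw:
        raise ValueError(f"channel mismatch: input has {Ci}, weights expect {Ciw}")
    d = int(dilation)
    Ho = H - (kh - 1) * d
    Wo = W - (kw - 1) * d
    if Ho < 1 or Wo < 1:
        raise ValueError("input smaller than the (dilated) kernel support")
    out = np.zeros((B, Co, Ho, Wo), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xd[:, :, i * d:i * d + Ho, j * d:j * d + Wo]
            out += np.moveaxis(np.tensordot(wd[:, :, i, j], xs, axes=(1, 1)), 0, 1)
    parents = [x, w]
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, Co, 1, 1)
        parents.append(bias)

    def backward(g):
        gx = np.zeros_like(xd)
        gw = np.zeros_like(wd)
        for i in range(kh):
            for j in range(kw):
                xs = xd[:, :, i * d:i * d + Ho, j * d:j * d + Wo]
                gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                gx[:, :, i * d:i * d + Ho, j * d:j * d + Wo] += np.moveaxis(
                    np.tensordot(wd[:, :, i, j], g, axes=(0, 1)), 0, 1
                )
        _accumulate(x, gx)
        _accumulate(w, gw)
        if bias is not None:
            _accumulate(bias, g.sum(axis=(0, 2, 3)))

    return _make(out, tuple(parents), backward)
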