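"""Layers, differentiable blur operations and the Adam optimizer.

Layer parameters are He-initialized from a caller-supplied numpy Generator so
that model construction is fully reproducible.  The differentiable blur
primitives mirror :mod:`cbaseg.blur_ops` tap for tap (same padding indices,
same binomial rows), so properties verified on the numpy functions carry
over to the trained network.
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .blur_ops import BlurKernel, make_blur_kernel, pad_indices

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "Adam",
    "t_blur_filter",
    "t_blur_downsample",
    "t_dense_max_2x2",
    "t_blur_max_pool",
    "t_pad",
    "t_resize_nearest",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class; submodules and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class Conv2d(Module):
    """'Same' convolution; padding is reflect by default, zero for dilated taps."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
        pad_mode: str = "reflect",
    ):
        k = kernel_size
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch))
        self.kernel_size = k
        self.dilation = dilation
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        k, d = self.kernel_size, self.dilation
        lo = (k - 1) // 2 * d
        hi = k // 2 * d
        if lo or hi:
            x = t_pad(x, lo, hi, lo, hi, mode=self.pad_mode)
        return T.conv2d(x, self.weight, self.bias, dilation=d)


class ConvTranspose2d(Module):
    """3x3 transpose convolution with stride 2: exactly doubles H and W."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_ch * 9))
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, 3, 3)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        # zero-stuff to 2H-1, zero-pad (1 top/left, 2 bottom/right), valid 3x3
        xd = T.dilate2(x)
        xp = T.pad_zero2d(xd, 1, 2, 1, 2)
        return T.conv2d(xp, self.weight, self.bias)


# ---------------------------------------------------------------------------
# differentiable blur primitives
# ---------------------------------------------------------------------------

def t_pad(x: Tensor, lo_h: int, hi_h: int, lo_w: int, hi_w: int, mode: str = "reflect") -> Tensor:
    if mode == "zero":
        return T.pad_zero2d(x, lo_h, hi_h, lo_w, hi_w)
    iy = pad_indices(x.shape[-2], lo_h, hi_h, mode)
    ix = pad_indices(x.shape[-1], lo_w, hi_w, mode)
    return T.gather2d(x, iy, ix)


def t_blur_filter(x: Tensor, kernel: BlurKernel) -> Tensor:
    k = kernel.size
    if k == 1:
        return x
    lo, hi = (k - 1) // 2, k // 2
    xp = t_pad(x, lo, hi, lo, hi, mode="reflect")
    return T.sep_correlate_valid(xp, kernel.row)


def t_blur_downsample(x: Tensor, kernel: BlurKernel, stride: int) -> Tensor:
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    y = t_blur_filter(x, kernel)
    if stride == 1:
        return y
    return y[:, :, ::stride, ::stride]


def t_dense_max_2x2(x: Tensor) -> Tensor:
    H, W = x.shape[-2:]
    xp = t_pad(x, 0, 1, 0, 1, mode="edge")
    out = T.maximum(xp[:, :, :H, :W], xp[:, :, 1:H + 1, :W])
    out = T.maximum(out, xp[:, :, :H, 1:W + 1])
    return T.maximum(out, xp[:, :, 1:H + 1, 1:W + 1])


def t_blur_max_pool(x: Tensor, kernel: BlurKernel, stride: int = 2) -> Tensor:
    return t_blur_downsample(t_dense_max_2x2(x), kernel, stride)


def t_resize_nearest(x: Tensor, out_h: int, out_w: int) -> Tensor:
    H, W = x.shape[-2:]
    iy = (np.arange(out_h) * H // out_h).astype(np.intp)
    ix = (np.arange(out_w) * W // out_w).astype(np.intp)
    return T.gather2d(x, iy, ix)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
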