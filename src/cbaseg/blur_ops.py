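"""Anti-aliased pooling and convolution primitives.

Plain max pooling aliases: a one-pixel shift of the input can change which
samples survive subsampling, so downstream features jitter.  Blur pooling
decomposes pooling into a dense (stride-1) max, a binomial low-pass filter,
and naive subsampling; because the low-pass filter removes the frequencies
that subsampling would fold back, the pooled features move far less under
small input shifts.  Every downsampling step in the segmentation network is
built from the three primitives in this module.

All functions here operate on plain numpy ``(batch, channel, height, width)``
arrays and are dtype-preserving; the differentiable counterparts used inside
the network live in :mod:`cbaseg.nn` and share these conventions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

__all__ = [
    "BlurKernel",
    "make_blur_kernel",
    "pad_indices",
    "reflect_pad2d",
    "edge_pad2d",
    "blur_filter",
    "blur_downsample",
    "dense_max_2x2",
    "blur_max_pool",
    "blur_conv",
]


@dataclass(frozen=True)
class BlurKernel:
    """A normalized, separable binomial low-pass filter.

    ``weights`` is the outer product of the binomial row ``C(size-1, k)``
    with itself, normalized to unit sum, so constant (DC) signals pass
    through unchanged.
    """

    size: int
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.size, self.size):
            raise ValueError("weights shape must be (size, size)")
        if not np.isclose(w.sum(), 1.0, atol=1e-12):
            raise ValueError("blur kernel weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def row(self) -> np.ndarray:
        """The normalized 1-D binomial row (the kernel is separable)."""
        r = np.array([comb(self.size - 1, k, exact=True) for k in range(self.size)], dtype=np.float64)
        return r / r.sum()


def make_blur_kernel(size: int) -> BlurKernel:
    """Binomial low-pass kernel of the given side length.

    size=1 is the identity, size=2 the box average, size=3 the classic
    1/16 [[1,2,1],[2,4,2],[1,2,1]] filter.
    """
    if not isinstance(size, (int, np.integer)) or size <= 0:
        raise ValueError(f"blur kernel size must be a positive integer, got {size!r}")
    row = np.array([comb(size - 1, k, exact=True) for k in range(size)], dtype=np.float64)
    weights = np.outer(row, row)
    weights /= weights.sum()
    return BlurKernel(size=int(size), weights=weights)


# ---------------------------------------------------------------------------
# padding helpers
# ---------------------------------------------------------------------------

def pad_indices(n: int, lo: int, hi: int, mode: str = "reflect") -> np.ndarray:
    """Source indices for gather-style padding of a length-``n`` axis.

    ``reflect`` mirrors without repeating the edge sample; when the pad
    width reaches the axis length (tiny feature maps) it degrades to
    ``symmetric`` (edge sample repeated) so the result stays well defined.
    ``edge`` clamps to the border.
    """
    if n < 1:
        raise ValueError("cannot pad an empty axis")
    idx = np.arange(-lo, n + hi)
    if mode == "reflect":
        if max(lo, hi) < n:
            idx = np.abs(idx)
            idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
        else:  # symmetric fallback for degenerate sizes
            period = 2 * n
            idx = np.mod(idx, period)
            idx = np.where(idx >= n, period - 1 - idx, idx)
    elif mode == "edge":
        idx = np.clip(idx, 0, n - 1)
    else:
        raise ValueError(f"unknown padding mode {mode!r}")
    return idx.astype(np.intp)


def reflect_pad2d(x: np.ndarray, lo_h: int, hi_h: int, lo_w: int, hi_w: int) -> np.ndarray:
    iy = pad_indices(x.shape[-2], lo_h, hi_h, "reflect")
    ix = pad_indices(x.shape[-1], lo_w, hi_w, "reflect")
    return x[..., iy[:, None], ix[None, :]]


def edge_pad2d(x: np.ndarray, lo_h: int, hi_h: int, lo_w: int, hi_w: int) -> np.ndarray:
    iy = pad_indices(x.shape[-2], lo_h, hi_h, "edge")
    ix = pad_indices(x.shape[-1], lo_w, hi_w, "edge")
    return x[..., iy[:, None], ix[None, :]]


def _check_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"expected a (batch, channel, H, W) array, got ndim={x.ndim}")
    if x.shape[-2] < 1 or x.shape[-1] < 1:
        raise ValueError("feature map has empty spatial dimensions")
    return x


# ---------------------------------------------------------------------------
# the three blur primitives
# ---------------------------------------------------------------------------

def blur_filter(x: np.ndarray, kernel: BlurKernel) -> np.ndarray:
    """Separable low-pass filtering at stride 1, reflect-padded to keep size."""
    x = _check_feature_map(x)
    k = kernel.size
    if k == 1:
        return x.copy()
    lo, hi = (k - 1) // 2, k // 2
    xp = reflect_pad2d(x, lo, hi, 0, 0)
    row = kernel.row.astype(x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64)
    H, W = x.shape[-2:]
    out = np.zeros(x.shape[:-2] + (H, xp.shape[-1]), dtype=row.dtype)
    for i in range(k):
        out += row[i] * xp[..., i:i + H, :]
    outp = reflect_pad2d(out, 0, 0, lo, hi)
    res = np.zeros(x.shape[:-2] + (H, W), dtype=row.dtype)
    for j in range(k):
        res += row[j] * outp[..., :, j:j + W]
    return res


def blur_downsample(x: np.ndarray, kernel: BlurKernel, stride: int) -> np.ndarray:
    """Low-pass filter then subsample every ``stride`` pixels from index 0.

    Output spatial dims are ``ceil(in / stride)``; a stride of 1 applies the
    filter without subsampling.  Unit-sum weights preserve constants.
    """
    x = _check_feature_map(x)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return blur_filter(x, kernel)[..., ::stride, ::stride]


def dense_max_2x2(x: np.ndarray) -> np.ndarray:
    """Stride-1 2x2 max with edge padding on the bottom/right (size kept)."""
    x = _check_feature_map(x)
    xp = edge_pad2d(x, 0, 1, 0, 1)
    H, W = x.shape[-2:]
    out = xp[..., :H, :W]
    out = np.maximum(out, xp[..., 1:H + 1, :W])
    out = np.maximum(out, xp[..., :H, 1:W + 1])
    out = np.maximum(out, xp[..., 1:H + 1, 1:W + 1])
    return out


def blur_max_pool(x: np.ndarray, kernel: BlurKernel, stride: int = 2) -> np.ndarray:
    """Anti-aliased max pooling: dense 2x2 max, low-pass filter, subsample."""
    return blur_downsample(dense_max_2x2(x), kernel, stride)


def blur_conv(
    x: np.ndarray,
    weights: np.ndarray,
    stride: int,
    kernel: BlurKernel | None = None,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Convolution fused with blur pooling.

    The learned filter bank ``weights`` (out_ch, in_ch, kh, kw) is applied at
    stride 1 with reflect 'same' padding, then the result is anti-aliased and
    subsampled by ``stride``.  At stride 1 the low-pass filter is still
    applied, with no subsampling.
    """
    x = _check_feature_map(x)
    if stride not in (1, 2, 4, 8):
        raise ValueError(f"stride must be one of 1, 2, 4, 8, got {stride}")
    weights = np.asarray(weights)
    if weights.ndim != 4 or weights.shape[1] != x.shape[1]:
        raise ValueError("weights must be (out_ch, in_ch, kh, kw) matching input channels")
    if kernel is None:
        kernel = make_blur_kernel(3)
    kh, kw = weights.shape[2:]
    xp = reflect_pad2d(x, (kh - 1) // 2, kh // 2, (kw - 1) // 2, kw // 2)
    B, Ci, H, W = x.shape
    Co = weights.shape[0]
    out = np.zeros((B, Co, H, W), dtype=np.result_type(x.dtype, weights.dtype, np.float64))
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + H, j:j + W]
            out += np.moveaxis(np.tensordot(weights[:, :, i, j], xs, axes=(1, 1)), 0, 1)
    if bias is not None:
        out += np.asarray(bias).reshape(1, Co, 1, 1)
    return blur_downsample(out, kernel, stride)
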