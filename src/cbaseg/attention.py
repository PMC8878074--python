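"""The blur attention module: channel and spatial attention with blur pooling.

A CBAM-style refinement block in which one of the two pooled descriptor
paths is replaced by blur pooling.  Channel attention squeezes each channel
to a scalar two ways — a global spatial average, and repeated anti-aliased
max pooling down to 1x1 — pushes both through a shared two-layer MLP and
gates channels with the sigmoid of the sum.  Spatial attention collapses the
channel axis by mean and by max-followed-by-low-pass, filters the
two-plane stack with a learned 3x3 convolution and gates pixels with its
sigmoid.  The input is multiplied by the channel gate first, then by the
spatial gate.

The functional entry points accept either plain numpy (batch, channel, H, W)
arrays (returned as numpy) or autodiff tensors (returned as tensors, so the
module is trainable inside the network).
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .blur_ops import make_blur_kernel
from .nn import Conv2d, Linear, Module, t_blur_filter, t_blur_max_pool, t_pad

__all__ = [
    "BlurAttention",
    "channel_blur_attention",
    "spatial_blur_attention",
    "blur_attention_module",
]


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


class BlurAttention(Module):
    """Learned parameters of one blur attention block.

    Parameters
    ----------
    channels:
        Channel count of the feature map the block refines.
    mlp_ratio:
        Channel-reduction ratio r of the shared MLP; the hidden width is
        ``max(1, channels // r)``.
    blur_kernel_size:
        Side of the binomial low-pass filter used by every blur pooling.
    rng:
        Generator for weight initialization.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 mlp_ratio: int = 8, blur_kernel_size: int = 3):
        hidden = max(1, channels // mlp_ratio)
        self.channels = channels
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial_conv = Conv2d(2, 1, 3, rng)
        self.kernel = make_blur_kernel(blur_kernel_size)

    # -- descriptors ----------------------------------------------------
    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2(T.relu(self.fc1(x)))

    def _blur_descriptor(self, F: Tensor) -> Tensor:
        """Repeated stride-2 blur max pooling down to a 1x1 descriptor."""
        H, W = F.shape[-2:]
        ph, pw = _next_pow2(H), _next_pow2(W)
        if (ph, pw) != (H, W):
            F = t_pad(F, 0, ph - H, 0, pw - W, mode="reflect")
        while F.shape[-2] > 1 or F.shape[-1] > 1:
            F = t_blur_max_pool(F, self.kernel, stride=2)
        return T.reshape(F, (F.shape[0], F.shape[1]))

    # -- the three operations -------------------------------------------
    def channel_attention(self, F: Tensor) -> Tensor:
        """Per-channel gate sigma(MLP(avg) + MLP(blurpool)), shape (B, C, 1, 1)."""
        avg = T.tmean(F, axis=(2, 3))
        blur = self._blur_descriptor(F)
        gate = T.sigmoid(self._mlp(avg) + self._mlp(blur))
        return T.reshape(gate, (F.shape[0], F.shape[1], 1, 1))

    def spatial_attention(self, F: Tensor) -> Tensor:
        """Per-pixel gate from channel-mean and low-passed channel-max planes."""
        if F.shape[-2] < 3 or F.shape[-1] < 3:
            raise ValueError("spatial attention needs height and width >= 3")
        avg = T.tmean(F, axis=1, keepdims=True)
        mx = T.amax(F, axis=1, keepdims=True)
        blur = t_blur_filter(mx, self.kernel)
        return T.sigmoid(self.spatial_conv(T.concat([avg, blur], axis=1)))

    def forward(self, F: Tensor) -> Tensor:
        # both gates are computed from the incoming map and applied in
        # channel-then-spatial order: (M_cb * F) * M_sb
        return (F * self.channel_attention(F)) * self.spatial_attention(F)


# ---------------------------------------------------------------------------
# functional wrappers (numpy in -> numpy out, tensor in -> tensor out)
# ---------------------------------------------------------------------------

def _dispatch(F, fn):
    if isinstance(F, Tensor):
        return fn(F)
    out = fn(Tensor(np.asarray(F, dtype=np.float64)))
    return out.data


def channel_blur_attention(F, params: BlurAttention):
    """Channel gate of shape (batch, channel, 1, 1) with entries in (0, 1)."""
    return _dispatch(F, params.channel_attention)


def spatial_blur_attention(F, params: BlurAttention):
    """Spatial gate of shape (batch, 1, H, W) with entries in (0, 1)."""
    return _dispatch(F, params.spatial_attention)


def blur_attention_module(F, params: BlurAttention):
    """Channel-then-spatial gating; output has the shape of the input."""
    return _dispatch(F, params.forward)
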