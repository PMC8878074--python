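"""The convolutional blur attention (CBA) segmentation network.

Encoder–decoder with four anti-aliased downsampling (DN) blocks and four
upsampling (UP) blocks.  A stride-1 blur convolution (C1) lifts the
grayscale input to the base width; auxiliary blur convolutions at strides
2, 4 and 8 re-extract the C1 features at the three intermediate scales and
are concatenated with the matching DN outputs on the decoder side, so the
decoder sees both deeply processed and lightly processed views of every
scale.  Each DN block is a 3x3 convolution (doubling channels, capped),
a blur attention block and a stride-2 blur max pooling; each UP block is a
pyramid blur pooling (PBP) module followed by a 3x3 stride-2 transpose
convolution.  A 1x1 convolution and a sigmoid produce the per-pixel
foreground probability at full resolution.

For a 192x192 input the encoder sides run 192 -> 96 -> 48 -> 24 -> 12 and
the decoder restores 192.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _tensor as T
from ._tensor import Tensor
from .attention import BlurAttention
from .blur_ops import make_blur_kernel
from .nn import (
    Adam,  # noqa: F401  (re-exported convenience)
    Conv2d,
    ConvTranspose2d,
    Module,
    t_blur_downsample,
    t_blur_filter,
    t_blur_max_pool,
    t_pad,
    t_resize_nearest,
)

__all__ = [
    "NetworkConfig",
    "DNBlock",
    "PBPModule",
    "UPBlock",
    "CBANetwork",
    "build_cba_network",
    "dn_block",
    "up_block",
    "pbp_module",
    "aux_features",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """All architecture hyperparameters pinned in one place.

    ``input_size`` must be divisible by ``2**depth``.  Channel widths double
    at each DN block starting from ``base_channels`` and are capped at
    ``max_channels`` (default ``8 * base_channels``); the decoder halves
    them again with a floor of ``base_channels``.  ``pbp_bins`` are the
    pyramid grid sides; a bin larger than the map it is applied to is
    clamped to the map side.
    """

    input_size: int = 192
    input_channels: int = 1
    base_channels: int = 32
    depth: int = 4
    blur_kernel_size: int = 3
    mlp_ratio: int = 8
    pbp_bins: tuple = (1, 2, 4, 8)
    aux_strides: tuple = (2, 4, 8)
    max_channels: int | None = None

    def __post_init__(self):
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2 ** self.depth}"
            )
        if self.base_channels < 4 or self.base_channels % 4 != 0:
            raise ValueError("base_channels must be a positive multiple of 4")
        bins = tuple(self.pbp_bins)
        if any(b <= 0 for b in bins) or any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("pbp_bins must be strictly increasing positive integers")
        if tuple(self.aux_strides) != (2, 4, 8):
            raise ValueError("aux_strides are fixed at (2, 4, 8)")
        if self.max_channels is None:
            object.__setattr__(self, "max_channels", 8 * self.base_channels)

    # -- derived channel schedule ---------------------------------------
    def encoder_channels(self) -> list[int]:
        """Output width of C1 and of each DN block."""
        widths = [self.base_channels]
        for i in range(1, self.depth + 1):
            widths.append(min(self.base_channels * 2 ** i, self.max_channels))
        return widths

    def decoder_channels(self) -> list[int]:
        """Output width of each UP block, halving with a floor of base."""
        enc = self.encoder_channels()
        return [max(enc[self.depth - 1 - j] // 2, self.base_channels)
                for j in range(self.depth)]

    def to_yaml(self) -> str:
        d = {
            "input_size": self.input_size,
            "input_channels": self.input_channels,
            "base_channels": self.base_channels,
            "depth": self.depth,
            "blur_kernel_size": self.blur_kernel_size,
            "mlp_ratio": self.mlp_ratio,
            "pbp_bins": list(self.pbp_bins),
            "aux_strides": list(self.aux_strides),
            "max_channels": self.max_channels,
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text)
        d["pbp_bins"] = tuple(d["pbp_bins"])
        d["aux_strides"] = tuple(d["aux_strides"])
        return cls(**d)


class BlurConv(Module):
    """Learned 3x3 convolution + ReLU fused with blur downsampling (C1/C2/C4/C8)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng,
                 blur_kernel_size: int = 3):
        if stride not in (1, 2, 4, 8):
            raise ValueError(f"stride must be one of 1, 2, 4, 8, got {stride}")
        self.conv = Conv2d(in_ch, out_ch, 3, rng)
        self.stride = stride
        self.kernel = make_blur_kernel(blur_kernel_size)

    def forward(self, x: Tensor) -> Tensor:
        return t_blur_downsample(T.relu(self.conv(x)), self.kernel, self.stride)


class DNBlock(Module):
    """Downsampling block: widen, attend, anti-aliased pool (halves H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng, mlp_ratio: int = 8,
                 blur_kernel_size: int = 3):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)
        self.attention = BlurAttention(out_ch, rng, mlp_ratio=mlp_ratio,
                                       blur_kernel_size=blur_kernel_size)
        self.kernel = make_blur_kernel(blur_kernel_size)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        if H % 2 or W % 2:
            raise ValueError(f"DN block requires even spatial dims, got {H}x{W}")
        y = T.relu(self.conv(x))
        y = self.attention(y)
        return t_blur_max_pool(y, self.kernel, stride=2)


class PBPModule(Module):
    """Pyramid blur pooling: multi-scale context before each upsampling.

    The input is anti-aliased-pooled to each pyramid grid (1x1, 2x2, 4x4,
    8x8 by default; bins are clamped to the map side), filtered by a 3x3
    atrous blur convolution with dilation equal to the bin, resampled back
    to the input size by nearest neighbour, and concatenated with the
    input: C channels in, C + n_bins * (C // 4) out (2C for four bins).
    """

    def __init__(self, channels: int, rng, bins=(1, 2, 4, 8), blur_kernel_size: int = 3):
        if channels % 4 != 0:
            raise ValueError("PBP input channels must be divisible by 4")
        self.bins = tuple(bins)
        self.channels = channels
        self.kernel = make_blur_kernel(blur_kernel_size)
        # dilated taps reach outside tiny pooled grids, so branch convs zero-pad
        self.branch_convs = [
            Conv2d(channels, channels // 4, 3, rng, dilation=b, pad_mode="zero")
            for b in self.bins
        ]

    @property
    def out_channels(self) -> int:
        return self.channels + len(self.bins) * (self.channels // 4)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        outs = [x]
        for b, conv in zip(self.bins, self.branch_convs):
            bin_side = min(b, H, W)
            # pad to bin_side * 2^k >= side, then halve k times so every
            # pooling step keeps the dense-max + low-pass semantics
            k = 0
            while bin_side << k < max(H, W):
                k += 1
            target = bin_side << k
            y = x
            if (H, W) != (target, target):
                y = t_pad(y, 0, target - H, 0, target - W, mode="reflect")
            if k == 0:
                y = t_blur_max_pool(y, self.kernel, stride=1)
            for _ in range(k):
                y = t_blur_max_pool(y, self.kernel, stride=2)
            y = T.relu(conv(y))
            y = t_blur_filter(y, self.kernel)  # blur convolution at stride 1
            outs.append(t_resize_nearest(y, H, W))
        return T.concat(outs, axis=1)


class UPBlock(Module):
    """Upsampling block: multi-scale context, then a 3x3 stride-2 transpose conv."""

    def __init__(self, in_ch: int, out_ch: int, rng, bins=(1, 2, 4, 8),
                 blur_kernel_size: int = 3):
        self.pbp = PBPModule(in_ch, rng, bins=bins, blur_kernel_size=blur_kernel_size)
        self.up = ConvTranspose2d(self.pbp.out_channels, out_ch, rng)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        if skip is not None:
            if skip.shape[-2:] != x.shape[-2:]:
                raise ValueError(
                    f"skip spatial dims {skip.shape[-2:]} do not match decoder {x.shape[-2:]}"
                )
            x = T.concat([x, skip], axis=1)
        return T.relu(self.up(self.pbp(x)))


class CBANetwork(Module):
    """Full encoder–decoder; forward maps (B, Cin, S, S) -> (B, 1, S, S) in (0, 1)."""

    def __init__(self, config: NetworkConfig, init_seed: int = 0):
        rng = np.random.default_rng(init_seed)
        cfg = config
        self.config = cfg
        enc = cfg.encoder_channels()
        dec = cfg.decoder_channels()
        kws = dict(blur_kernel_size=cfg.blur_kernel_size)
        self.c1 = BlurConv(cfg.input_channels, enc[0], 1, rng, **kws)
        self.aux = [BlurConv(enc[0], cfg.base_channels, s, rng, **kws)
                    for s in cfg.aux_strides]
        self.dn = [DNBlock(enc[i], enc[i + 1], rng, mlp_ratio=cfg.mlp_ratio, **kws)
                   for i in range(cfg.depth)]
        # decoder input widths: bottleneck alone, then decoder + DN skip + aux skip
        up_in = [enc[cfg.depth]]
        for j in range(1, cfg.depth):
            up_in.append(dec[j - 1] + enc[cfg.depth - j] + cfg.base_channels)
        self.up = [UPBlock(c, dec[j], rng, bins=cfg.pbp_bins, **kws)
                   for j, c in enumerate(up_in)]
        self.head = Conv2d(dec[-1], 1, 1, rng)

    def forward(self, x) -> Tensor:
        x = T.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected (B, {self.config.input_channels}, S, S) input, got {x.shape}"
            )
        if x.shape[-2] % (2 ** self.config.depth) or x.shape[-1] % (2 ** self.config.depth):
            raise ValueError(
                f"spatial dims must be divisible by {2 ** self.config.depth}, got {x.shape[-2:]}"
            )
        c1 = self.c1(x)
        aux = [m(c1) for m in self.aux]
        feats = []
        y = c1
        for blk in self.dn:
            y = blk(y)
            feats.append(y)
        # decoder: bottleneck first, then skips at sides S/8, S/4, S/2
        y = self.up[0](feats[-1])
        for j in range(1, self.config.depth):
            dn_skip = feats[self.config.depth - 1 - j]
            aux_skip = aux[self.config.depth - 1 - j]
            skip = T.concat([dn_skip, aux_skip], axis=1)
            y = self.up[j](y, skip)
        return T.sigmoid(self.head(y))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass returning a numpy probability map (no graph kept)."""
        return self.forward(Tensor(np.asarray(x, dtype=np.float32))).data


def build_cba_network(config: NetworkConfig, init_seed: int = 0) -> CBANetwork:
    """Construct the network with reproducible parameter initialization."""
    return CBANetwork(config, init_seed=init_seed)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# functional wrappers over the blocks (numpy in -> numpy out)
# ---------------------------------------------------------------------------

def _apply(block, *arrays):
    tensors = [x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
               for x in arrays]
    out = block(*tensors)
    return out if isinstance(arrays[0], Tensor) else out.data


def dn_block(x, params: DNBlock):
    return _apply(params, x)


def pbp_module(x, params: PBPModule):
    return _apply(params, x)


def up_block(x, skip, params: UPBlock):
    if skip is None:
        return _apply(params, x)
    return _apply(params, x, skip)


def aux_features(c1_out, params):
    """Strided blur convolutions of the C1 features (sides S/2, S/4, S/8).

    ``params`` is either a built network or a sequence of three strided
    blur-convolution blocks.
    """
    blocks = params.aux if isinstance(params, CBANetwork) else list(params)
    return tuple(_apply(b, c1_out) for b in blocks)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: CBANetwork, path: str) -> None:
    """Write parameters to ``<path>.npz`` style file plus a YAML config sidecar."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    with open(path[:-4] + ".yaml", "w") as fh:
        fh.write(model.config.to_yaml())


def load_checkpoint(path: str) -> CBANetwork:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path[:-4] + ".yaml") as fh:
        config = NetworkConfig.from_yaml(fh.read())
    model = CBANetwork(config)
    with np.load(path) as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model
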