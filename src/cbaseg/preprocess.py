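"""Image normalization, wavelet denoising, tiling and augmentation.

The training pipeline normalizes microscopy images to grayscale in [0, 1]
at the network input size, optionally denoises them with a one-level
biorthogonal wavelet soft-threshold (a low-pass cleanup of sensor noise),
cuts large slides into non-overlapping patches, and feeds the network from
a seeded, endless augmentation stream (rotations, flips, random crops) so
no two draws are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pywt
import tifffile
from scipy import ndimage as ndi
from skimage.transform import resize, rotate

__all__ = [
    "PatchGrid",
    "normalize_image",
    "wavelet_lowpass",
    "tile_image",
    "assemble_tiles",
    "augment_stream",
    "make_epoch",
    "read_image",
    "read_label_mask",
    "read_dsb_masks",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R 601


@dataclass(frozen=True)
class PatchGrid:
    """Row-major layout of non-overlapping patches covering a (padded) image."""

    source_shape: tuple
    patch_size: int
    rows: int
    cols: int
    pad_bottom: int
    pad_right: int

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    def offsets(self):
        """(row index, col index, y0, x0) for every patch, row-major, 0-based."""
        P = self.patch_size
        return [(r, c, r * P, c * P) for r in range(self.rows) for c in range(self.cols)]


def _to_float(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    img = img.astype(np.float64)
    mx = img.max() if img.size else 1.0
    if mx > 1.0:
        img = img / mx
    return img


def normalize_image(img: np.ndarray, out_size: int = 192) -> np.ndarray:
    """Grayscale conversion, bilinear resize to ``out_size`` square, range [0, 1].

    Accepts 2-D grayscale or (H, W, 3|4) color arrays; alpha is dropped and
    RGB collapses to luminance with ITU-R 601 weights.  Idempotent on
    already-normalized inputs.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[..., :3]
        if img.shape[2] == 3:
            img = _to_float(img) @ _LUMA
        elif img.shape[2] == 1:
            img = _to_float(img[..., 0])
        else:
            raise ValueError(f"unsupported channel count {img.shape[2]}")
    elif img.ndim == 2:
        img = _to_float(img)
    else:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    if img.shape != (out_size, out_size):
        img = resize(img, (out_size, out_size), order=1, mode="reflect",
                     anti_aliasing=img.shape[0] > out_size, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def wavelet_lowpass(img: np.ndarray, wavelet: str = "bior1.3") -> np.ndarray:
    """One-level biorthogonal wavelet soft-threshold denoising.

    The detail subbands are soft-thresholded at the universal threshold
    sigma * sqrt(2 ln N), with sigma estimated from the median absolute
    deviation of the diagonal subband (MAD / 0.6745); the approximation
    band passes through, making this a data-adaptive low-pass filter.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("wavelet_lowpass expects a single-channel image")
    wav = pywt.Wavelet(wavelet)
    if min(img.shape) < 2 * wav.dec_len:
        warnings.warn("image smaller than the wavelet filter support; returned unchanged")
        return img.copy()
    cA, (cH, cV, cD) = pywt.dwt2(img, wav, mode="symmetric")
    sigma = np.median(np.abs(cD)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(img.size))
    if thr > 0:
        details = tuple(pywt.threshold(c, thr, mode="soft") for c in (cH, cV, cD))
    else:  # noise-free (e.g. constant) input: nothing to threshold
        details = (cH, cV, cD)
    out = pywt.idwt2((cA, details), wav, mode="symmetric")
    out = out[: img.shape[0], : img.shape[1]]
    return np.clip(out, 0.0, 1.0)


def tile_image(img: np.ndarray, mask: np.ndarray | None = None, patch: int = 250):
    """Cut an image (and optional instance mask) into non-overlapping tiles.

    A 1000x1000 slide with the default 250-pixel patch yields 16 tiles.
    Sides not divisible by ``patch`` are reflect-padded (recorded in the
    returned grid).  Instance labels in each mask tile are relabeled to a
    contiguous 1..k.  Returns ``(tiles, grid)`` where each tile is the
    image patch or an (image, mask) pair when a mask is given.
    """
    img = np.asarray(img)
    if patch < 1:
        raise ValueError("patch size must be positive")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != img.shape[:2]:
            raise ValueError(f"mask shape {mask.shape} does not match image {img.shape[:2]}")
    H, W = img.shape[:2]
    pad_b = -H % patch
    pad_r = -W % patch
    grid = PatchGrid(source_shape=(H, W), patch_size=patch,
                     rows=(H + pad_b) // patch, cols=(W + pad_r) // patch,
                     pad_bottom=pad_b, pad_right=pad_r)
    if pad_b or pad_r:
        pad_width = [(0, pad_b), (0, pad_r)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad_width, mode="reflect")
        if mask is not None:
            # labels must stay integral: pad with background, not reflections
            mask = np.pad(mask, [(0, pad_b), (0, pad_r)], mode="constant")
    tiles = []
    for _, _, y0, x0 in grid.offsets():
        ip = img[y0:y0 + patch, x0:x0 + patch]
        if mask is None:
            tiles.append(ip)
        else:
            mp = relabel_sequential(mask[y0:y0 + patch, x0:x0 + patch])
            tiles.append((ip, mp))
    return tiles, grid


def relabel_sequential(mask: np.ndarray) -> np.ndarray:
    """Map the positive labels of an instance map onto contiguous 1..k."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask)
    for new, old in enumerate(labels, start=1):
        out[mask == old] = new
    return out


def assemble_tiles(tiles, grid: PatchGrid) -> np.ndarray:
    """Invert :func:`tile_image` (image part only); crops any padding."""
    P = grid.patch_size
    first = tiles[0][0] if isinstance(tiles[0], tuple) else tiles[0]
    H = grid.rows * P
    W = grid.cols * P
    out = np.zeros((H, W) + first.shape[2:], dtype=first.dtype)
    for (r, c, y0, x0), t in zip(grid.offsets(), tiles):
        patch = t[0] if isinstance(t, tuple) else t
        out[y0:y0 + P, x0:x0 + P] = patch
    h, w = grid.source_shape
    return out[:h, :w]


def _random_crop(img, mask, size, rng):
    H, W = img.shape[:2]
    if H < size or W < size:
        pad_b = max(0, size - H)
        pad_r = max(0, size - W)
        img = np.pad(img, [(0, pad_b), (0, pad_r)], mode="reflect")
        mask = np.pad(mask, [(0, pad_b), (0, pad_r)], mode="constant")
        H, W = img.shape[:2]
    y = int(rng.integers(0, H - size + 1))
    x = int(rng.integers(0, W - size + 1))
    return img[y:y + size, x:x + size], mask[y:y + size, x:x + size]


def augment_stream(dataset, seed: int, out_size: int = 192,
                   free_angle_prob: float = 0.5):
    """Endless seeded generator of augmented (image, instance-mask) pairs.

    Each draw picks a base pair, applies a random 0/90/180/270 rotation,
    optionally a free-angle rotation (image bilinear with reflect fill,
    mask nearest-neighbour so labels stay integral), random flips, and a
    random crop to ``out_size``.  Identical seeds give identical streams.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    while True:
        img, mask = dataset[int(rng.integers(len(dataset)))]
        img = np.asarray(img, dtype=np.float64)
        mask = np.asarray(mask)
        k = int(rng.integers(4))
        if k:
            img = np.rot90(img, k)
            mask = np.rot90(mask, k)
        if rng.random() < free_angle_prob:
            angle = float(rng.uniform(0.0, 360.0))
            img = rotate(img, angle, mode="reflect", order=1, preserve_range=True)
            mask = ndi.rotate(mask, angle, order=0, reshape=False, mode="constant")
        if rng.random() < 0.5:
            img = img[:, ::-1]
            mask = mask[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1]
            mask = mask[::-1]
        img, mask = _random_crop(np.ascontiguousarray(img),
                                 np.ascontiguousarray(mask), out_size, rng)
        yield img.copy(), relabel_sequential(mask)


def make_epoch(dataset, epoch_size: int, seed: int, out_size: int = 192,
               free_angle_prob: float = 0.5):
    """A fixed-size list of augmented pairs (e.g. 536 slides -> a 2372-crop epoch)."""
    stream = augment_stream(dataset, seed, out_size=out_size,
                            free_angle_prob=free_angle_prob)
    return [next(stream) for _ in range(epoch_size)]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        return tifffile.imread(path)
    return iio.imread(path)


def read_label_mask(path) -> np.ndarray:
    """A single integer instance-label image (16-bit TIFF or PNG)."""
    arr = read_image(path)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be single-channel, got shape {arr.shape}")
    return arr.astype(np.int32)


def read_dsb_masks(mask_dir) -> np.ndarray:
    """Union of per-instance binary masks (one file per nucleus).

    This is the 2018 Data Science Bowl layout: a ``masks/`` directory of
    binary PNGs.  Files are combined in sorted order into one instance
    label map; overlapping instances raise.
    """
    from pathlib import Path

    files = sorted(p for p in Path(mask_dir).iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not files:
        raise ValueError(f"no mask files in {mask_dir}")
    out = None
    for i, f in enumerate(files, start=1):
        m = read_image(f)
        if m.ndim == 3:
            m = m[..., 0]
        m = m > 0
        if out is None:
            out = np.zeros(m.shape, dtype=np.int32)
        if (out[m] != 0).any():
            raise ValueError(f"instance masks overlap at {f}")
        out[m] = i
    return out
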