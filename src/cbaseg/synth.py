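"""Seeded synthetic nuclei-scene generator.

Renders microscopy-like scenes with exact instance ground truth so every
stage of the pipeline is testable without external data.  Two modes:

* ``fluorescence`` — bright elliptical nuclei on a dark background with a
  smooth multiplicative illumination gradient and sensor noise (grayscale),
  emulating DAPI/Hoechst-stained fields with heterogeneous illumination;
* ``histology`` — hematoxylin-like purple nuclei on an eosin-like pink
  textured background (RGB), emulating stained tissue with touching nuclei.

Nuclei are rejection-sampled ellipses.  A configurable fraction is placed
next to an existing nucleus so instances touch; label maps never overlap —
contested pixels stay with the earlier nucleus — so the ground truth is
exact and touching nuclei keep distinct labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
import tifffile

__all__ = ["SceneConfig", "generate_scene", "generate_dataset", "load_corpus"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene family.

    Defaults describe a plausible fluorescence field of view: a 256-pixel
    square with 8–18 nuclei of 5–12 px mean radius, mild eccentricity, a
    quarter of nuclei seeded against an existing one (touching clusters),
    ±25% smooth illumination, and Gaussian read noise (sigma = 0.03).
    """

    size: tuple = (256, 256)
    n_range: tuple = (8, 18)
    radius_range: tuple = (5.0, 12.0)
    eccentricity_range: tuple = (1.0, 1.6)
    cluster_prob: float = 0.25
    illumination: float = 0.25
    gauss_sigma: float = 0.03
    poisson_scale: float = 0.0
    mode: str = "fluorescence"
    seed: int = 0
    antialias: bool = False

    def __post_init__(self):
        if self.n_range[0] > self.n_range[1] or self.n_range[0] < 0:
            raise ValueError("invalid nucleus count range")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("invalid radius range")
        if not (0.0 <= self.cluster_prob <= 1.0):
            raise ValueError("cluster_prob must be in [0, 1]")
        if self.mode not in ("fluorescence", "histology"):
            raise ValueError("mode must be 'fluorescence' or 'histology'")


def _ellipse_mask(shape, cy, cx, a, b, theta) -> np.ndarray:
    """Pixels whose centers fall inside the rotated ellipse (center-in-pixel)."""
    H, W = shape
    y0 = max(0, int(np.floor(cy - max(a, b) - 1)))
    y1 = min(H, int(np.ceil(cy + max(a, b) + 2)))
    x0 = max(0, int(np.floor(cx - max(a, b) - 1)))
    x1 = min(W, int(np.ceil(cx + max(a, b) + 2)))
    if y0 >= y1 or x0 >= x1:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def _smooth_field(shape, rng, n_blobs: int = 3) -> np.ndarray:
    """Zero-mean smooth random field in [-1, 1] (sum of broad Gaussians)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    f = np.zeros(shape)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        s = rng.uniform(0.4, 0.9) * max(H, W)
        amp = rng.uniform(-1.0, 1.0)
        f += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
    mx = np.abs(f).max()
    if mx > 0:
        f /= mx
    return f - f.mean()


def generate_scene(config: SceneConfig):
    """Render one scene; returns (image, label map, info dict).

    The image is float64 in [0, 1], grayscale ``(H, W)`` in fluorescence
    mode or RGB ``(H, W, 3)`` in histology mode.  The label map is int32
    with contiguous labels 1..L.  ``info['short']`` flags infeasible
    packing (fewer nuclei placed than requested).
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.size
    labels = np.zeros((H, W), dtype=np.int32)
    n_target = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
    centers: list[tuple[float, float, float]] = []
    placed = 0
    for _ in range(n_target):
        r = rng.uniform(*config.radius_range)
        ecc = rng.uniform(*config.eccentricity_range)
        a, b = r * np.sqrt(ecc), r / np.sqrt(ecc)
        theta = rng.uniform(0, np.pi)
        ok = False
        for _try in range(60):
            clustered = bool(centers) and rng.random() < config.cluster_prob
            if clustered:
                cy0, cx0, r0 = centers[int(rng.integers(len(centers)))]
                d = (r0 + r) * rng.uniform(0.95, 1.1)
                ang = rng.uniform(0, 2 * np.pi)
                cy = cy0 + d * np.sin(ang)
                cx = cx0 + d * np.cos(ang)
            else:
                cy = rng.uniform(a, H - a)
                cx = rng.uniform(a, W - a)
            if not (0 <= cy < H and 0 <= cx < W):
                continue
            m = _ellipse_mask((H, W), cy, cx, a, b, theta)
            area = int(m.sum())
            if area == 0:
                continue
            if clustered:
                # touching allowed: small overlaps are trimmed, contested
                # pixels stay with the earlier nucleus
                overlap = int((labels[m] > 0).sum())
                if overlap > 0.15 * area:
                    continue
                m = m & (labels == 0)
                if m.sum() < 0.5 * area:
                    continue
            else:
                # isolated placement: at least one background pixel of
                # separation so only clustered nuclei ever touch
                if (labels[ndi.binary_dilation(m)] > 0).any():
                    continue
            placed += 1
            labels[m] = placed
            centers.append((cy, cx, r))
            ok = True
            break
        if not ok:
            continue
    short = placed < n_target
    if short:
        warnings.warn(f"placed {placed}/{n_target} nuclei (packing infeasible)")

    # -- rendering ------------------------------------------------------
    if config.mode == "fluorescence":
        img = np.full((H, W), 0.08)
        for lab in range(1, placed + 1):
            img[labels == lab] = rng.uniform(0.55, 0.95)
        if config.illumination > 0:
            img *= 1.0 + config.illumination * _smooth_field((H, W), rng)
        if config.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * config.poisson_scale) / config.poisson_scale
        if config.gauss_sigma > 0:
            img += rng.normal(0.0, config.gauss_sigma, size=(H, W))
        img = np.clip(img, 0.0, 1.0)
    else:  # histology: eosin-pink background, hematoxylin-purple nuclei
        background = np.array([0.91, 0.76, 0.85])
        nucleus = np.array([0.38, 0.25, 0.58])
        img = np.empty((H, W, 3))
        img[:] = background
        texture = _smooth_field((H, W), rng)
        img += 0.05 * texture[..., None]
        for lab in range(1, placed + 1):
            tint = nucleus * rng.uniform(0.85, 1.15)
            img[labels == lab] = np.clip(tint, 0, 1)
        if config.illumination > 0:
            img *= 1.0 + config.illumination * _smooth_field((H, W), rng)[..., None]
        if config.gauss_sigma > 0:
            img += rng.normal(0.0, config.gauss_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
    return img, labels, {"short": short, "n_placed": placed, "n_target": n_target}


def generate_dataset(config: SceneConfig, n: int, out_dir) -> pd.DataFrame:
    """Write ``n`` scenes (PNG image + 16-bit label TIFF) plus a manifest CSV.

    Per-scene seeds are derived deterministically from ``config.seed``, so
    the same master seed reproduces a byte-identical corpus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        child_seed = int(np.random.SeedSequence((config.seed, i)).generate_state(1)[0])
        scene_cfg = replace(config, seed=child_seed)
        img, labels, info = generate_scene(scene_cfg)
        stem = f"scene_{i:04d}"
        img_path = out_dir / f"{stem}.png"
        lab_path = out_dir / f"{stem}_labels.tif"
        iio.imwrite(img_path, np.round(img * 255).astype(np.uint8))
        tifffile.imwrite(lab_path, labels.astype(np.uint16))
        rows.append({
            "scene_id": stem,
            "image": img_path.name,
            "labels": lab_path.name,
            "n_instances": info["n_placed"],
            "seed": child_seed,
            "short": info["short"],
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_corpus(corpus_dir):
    """Read a generated corpus back as a list of (image, label map) pairs."""
    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    pairs = []
    for _, row in manifest.iterrows():
        img = iio.imread(corpus_dir / row["image"])
        labels = tifffile.imread(corpus_dir / row["labels"]).astype(np.int32)
        pairs.append((img, labels))
    return pairs
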