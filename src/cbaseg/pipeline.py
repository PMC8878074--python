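"""Training (pretrain + fine-tune), prediction and corpus evaluation.

The training loss is binary cross-entropy plus soft-Dice (equal weights),
optimized with Adam.  Runs are seeded end to end: corpus order, batch
shuffling and parameter initialization all derive from the configured
seeds, so identical configurations reproduce identical loss histories.

Pretraining follows the small-data recipe: fit first on a surrogate corpus
(by default synthetic fluorescence scenes), then continue on the target
corpus from the pretrained weights.  Both phases are logged separately.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .metrics import MetricsReport, evaluate_pair, instances_from_probability, metrics_table
from .network import CBANetwork, NetworkConfig, build_cba_network
from .nn import Adam
from .preprocess import normalize_image, read_label_mask, wavelet_lowpass
from .synth import SceneConfig, generate_scene, load_corpus

__all__ = [
    "TrainConfig",
    "train",
    "pretrain_finetune",
    "predict",
    "evaluate",
    "prepare_pairs",
    "synthetic_corpus",
]


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    lr: float = 1e-3
    optimizer: str = "adam"
    loss: str = "bce+dice"
    patience: int = 10
    seed: int = 0
    pretrain: str | None = None       # None, 'synthetic', or a corpus directory
    finetune: str | None = None       # corpus directory for the fine-tune phase
    val_fraction: float = 0.2
    pretrain_epochs: int | None = None
    pretrain_size: int = 64           # scenes in the synthetic pretrain corpus
    denoise: bool = False             # wavelet low-pass before resizing

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def prepare_pairs(pairs, input_size: int, denoise: bool = False):
    """Convert (image, instance-label) pairs to network-ready arrays.

    Images become grayscale float [0, 1] at ``input_size``; labels are
    nearest-resampled when the size differs (labels stay integral).  With
    ``denoise`` the biorthogonal-wavelet low-pass runs after grayscale
    conversion and before resizing.  Returns a list of
    (image, instance labels, binary target).
    """
    out = []
    for img, labels in pairs:
        g = np.asarray(img)
        if denoise:
            from .preprocess import _to_float, _LUMA

            g = _to_float(g)
            if g.ndim == 3:
                g = g[..., :3] @ _LUMA
            g = wavelet_lowpass(g)
        g = normalize_image(g, out_size=input_size)
        labels = np.asarray(labels)
        if labels.shape != g.shape:
            iy = (np.arange(input_size) * labels.shape[0] // input_size)
            ix = (np.arange(input_size) * labels.shape[1] // input_size)
            labels = labels[iy[:, None], ix[None, :]]
        out.append((g.astype(np.float32), labels.astype(np.int32),
                    (labels > 0).astype(np.float32)))
    return out


def synthetic_corpus(n: int, size: int, seed: int, mode: str = "fluorescence",
                     **scene_kwargs):
    """n in-memory scenes with per-scene seeds derived from ``seed``."""
    pairs = []
    for i in range(n):
        child = int(np.random.SeedSequence((seed, i)).generate_state(1)[0])
        cfg = SceneConfig(size=(size, size), mode=mode, seed=child, **scene_kwargs)
        img, labels, _ = generate_scene(cfg)
        pairs.append((img, labels))
    return pairs


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_soft_dice(probs: Tensor, target: np.ndarray) -> Tensor:
    """Binary cross-entropy + (1 - soft Dice), equal weights."""
    t = Tensor(np.asarray(target, dtype=np.float32))
    one_minus_p = probs * (-1.0) + 1.0
    one_minus_t = t * (-1.0) + 1.0
    bce = T.tmean(t * T.log(probs) + one_minus_t * T.log(one_minus_p)) * (-1.0)
    inter = T.tsum(probs * t)
    denom = T.tsum(probs) + T.tsum(t) + 1e-6
    soft_dice = (inter * 2.0) * T.power(denom, -1.0)
    return bce + (soft_dice * (-1.0) + 1.0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_loss(model, imgs, targets) -> Tensor:
    x = np.stack(imgs)[:, None]  # (B, 1, H, W)
    probs = model.forward(Tensor(x))
    return bce_soft_dice(probs, np.stack(targets)[:, None])


def train(model: CBANetwork, dataset, config: TrainConfig):
    """Optimize ``model`` on (image, labels) pairs; returns (model, history).

    ``dataset`` is a list of (image, instance-label) pairs, or a corpus
    directory path.  The best-validation-loss parameters are restored at
    the end; training aborts with a diagnostic if the loss goes non-finite.
    """
    if isinstance(dataset, (str, Path)):
        dataset = load_corpus(dataset)
    if len(dataset) == 0:
        raise ValueError("training corpus is empty")
    data = prepare_pairs(dataset, model.config.input_size, denoise=config.denoise)
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(data))
    n_val = max(1, int(round(config.val_fraction * len(data)))) if len(data) > 1 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = idx, idx[:0]
    opt = Adam(model.parameters(), lr=config.lr)
    history = {"train_loss": [], "val_loss": [],
               "val_indices": [int(i) for i in val_idx],
               "train_indices": [int(i) for i in train_idx]}
    best_loss = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    since_best = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            imgs = [data[i][0] for i in batch]
            tgts = [data[i][2] for i in batch]
            loss = _forward_loss(model, imgs, tgts)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {_epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses)) if losses else np.nan
        if len(val_idx):
            val_losses = []
            for start in range(0, len(val_idx), config.batch_size):
                batch = val_idx[start:start + config.batch_size]
                vl = _forward_loss(model, [data[i][0] for i in batch],
                                   [data[i][2] for i in batch])
                val_losses.append(float(vl.data))
            val_loss = float(np.mean(val_losses))
        else:
            val_loss = train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.load_state_arrays(best_state)
    history["best_val_loss"] = best_loss if np.isfinite(best_loss) else np.nan
    return model, history


def pretrain_finetune(net_config: NetworkConfig, config: TrainConfig,
                      pretrain_data=None, finetune_data=None, init_seed: int = 0):
    """Pretrain on a surrogate corpus, then fine-tune on the target corpus.

    The pretrain corpus comes from ``pretrain_data``, a corpus directory in
    ``config.pretrain``, or (with ``config.pretrain == 'synthetic'``) an
    in-memory synthetic corpus.  ``config.pretrain`` left as None skips the
    pretraining phase entirely.  Returns (model, history) with separate
    'pretrain' and 'finetune' histories.
    """
    model = build_cba_network(net_config, init_seed=init_seed)
    history: dict = {"pretrain": None, "finetune": None}
    if config.pretrain is not None:
        if pretrain_data is not None:
            pre = pretrain_data
        elif config.pretrain == "synthetic":
            pre = synthetic_corpus(config.pretrain_size, net_config.input_size,
                                   seed=config.seed + 1)
        else:
            pre = load_corpus(config.pretrain)
        pre_epochs = (config.pretrain_epochs if config.pretrain_epochs is not None
                      else config.epochs)
        pre_cfg = dataclasses.replace(config, epochs=pre_epochs)
        model, history["pretrain"] = train(model, pre, pre_cfg)
    if finetune_data is None:
        if config.finetune is None:
            raise ValueError("no fine-tune corpus configured")
        finetune_data = load_corpus(config.finetune)
    if config.epochs > 0:
        model, history["finetune"] = train(model, finetune_data, config)
    return model, history


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: CBANetwork, image, threshold: float = 0.5, min_size: int = 4):
    """Probability map and instance labels for one image of any size.

    Inputs at the network size are forwarded directly; larger images are
    reflect-padded to a multiple of the network size, predicted tile by
    tile and stitched back.  Deterministic for a fixed model and image.
    """
    S = model.config.input_size
    img = _to_gray(np.asarray(image))
    H, W = img.shape
    if (H, W) == (S, S):
        prob = model.predict(img[None, None].astype(np.float32))[0, 0]
    else:
        pad_b, pad_r = -H % S, -W % S
        padded = np.pad(img, [(0, pad_b), (0, pad_r)], mode="reflect")
        Hp, Wp = padded.shape
        prob = np.zeros((Hp, Wp), dtype=np.float32)
        tiles = []
        coords = []
        for y0 in range(0, Hp, S):
            for x0 in range(0, Wp, S):
                tiles.append(padded[y0:y0 + S, x0:x0 + S])
                coords.append((y0, x0))
        batch = np.stack(tiles)[:, None].astype(np.float32)
        out = model.predict(batch)
        for (y0, x0), p in zip(coords, out[:, 0]):
            prob[y0:y0 + S, x0:x0 + S] = p
        prob = prob[:H, :W]
    labels = instances_from_probability(prob, threshold=threshold, min_size=min_size)
    return prob, labels


def _to_gray(img):
    from .preprocess import _LUMA, _to_float

    if img.ndim == 3:
        return _to_float(img[..., :3]) @ _LUMA
    return _to_float(img)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(pred_dir, truth_dir, out_csv=None):
    """Per-image metrics for matching label files in two directories.

    Files are matched by name; unmatched files are returned for the caller
    to report.  Returns (DataFrame, unmatched list); the frame has one row
    per image plus an unweighted-mean 'aggregate' row.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    exts = (".png", ".tif", ".tiff")
    preds = {p.stem: p for p in pred_dir.iterdir() if p.suffix.lower() in exts}
    truths = {p.stem: p for p in truth_dir.iterdir() if p.suffix.lower() in exts}
    common = sorted(set(preds) & set(truths))
    unmatched = sorted(set(preds) ^ set(truths))
    reports: dict[str, MetricsReport] = {}
    for name in common:
        reports[name] = evaluate_pair(read_label_mask(truths[name]),
                                      read_label_mask(preds[name]))
    if not reports:
        raise ValueError("no matching prediction/truth files")
    df = metrics_table(reports)
    if out_csv is not None:
        df.to_csv(out_csv)
    return df, unmatched
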