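"""Pixel- and object-level segmentation metrics.

Pixel level: Dice similarity coefficient DSC = 2|A∩B| / (|A| + |B|), plus
precision TP/(TP+FP), recall TP/(TP+FN) and their harmonic mean F1.

Object level: the aggregated Jaccard index (AJI).  Ground-truth nuclei are
visited in ascending label order; each is matched to the still-unmatched
predicted nucleus with the greatest Jaccard overlap (ties go to the lowest
predicted label).  Matched pairs contribute |G∩P| to the numerator and
|G∪P| to the denominator; unmatched ground truth adds |G| and every
unmatched prediction adds |P| to the denominator, so both over- and
under-segmentation pull the score down.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import sparse
from skimage.measure import label as cc_label

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dice",
    "confusion_counts",
    "pixel_prf",
    "aji",
    "aji_parts",
    "dataset_aji",
    "instances_from_probability",
    "evaluate_pair",
    "metrics_table",
]

CSV_COLUMNS = ["dsc", "f1", "recall", "precision", "aji"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    dsc: float
    f1: float
    precision: float
    recall: float
    aji: float


def _as_bool(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(A, B) -> float:
    """DSC = 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    A, B = _as_bool(A, B)
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (sa + sb)


def confusion_counts(pred, truth) -> ConfusionCounts:
    pred, truth = _as_bool(pred, truth)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def pixel_prf(pred, truth) -> tuple[float, float, float]:
    """(precision, recall, F1) with the conventions: precision = 1 when no
    predicted positives, recall = 1 when no true positives, F1 = 0 when
    precision + recall = 0."""
    c = confusion_counts(pred, truth)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 1.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return precision, recall, f1


def _check_labels(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2 or not np.issubdtype(m.dtype, np.integer):
        m = np.asarray(m, dtype=np.int64)
        if m.ndim != 2:
            raise ValueError("instance label maps must be 2-D integer arrays")
    if (m < 0).any():
        raise ValueError("instance labels must be nonnegative")
    return m


def aji_parts(truth, pred) -> tuple[int, int]:
    """(numerator, denominator) of the aggregated Jaccard index."""
    truth = _check_labels(truth)
    pred = _check_labels(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    gt_labels = np.unique(truth)
    gt_labels = gt_labels[gt_labels > 0]
    pr_labels = np.unique(pred)
    pr_labels = pr_labels[pr_labels > 0]
    t_counts = np.bincount(truth.ravel())
    p_counts = np.bincount(pred.ravel())
    gt_sizes = {int(g): int(t_counts[g]) for g in gt_labels}
    pr_sizes = {int(p): int(p_counts[p]) for p in pr_labels}
    # sparse contingency of co-occurring (gt, pred) label pairs
    cont = sparse.coo_matrix(
        (np.ones(truth.size, dtype=np.int64), (truth.ravel(), pred.ravel()))
    ).tocsr()
    used: set[int] = set()
    num = 0
    den = 0
    for g in gt_labels:
        g = int(g)
        row = cont.getrow(g)
        best_p, best_j, best_inter = None, -1.0, 0
        # csr indices are ascending, so on exact Jaccard ties the first
        # (lowest) predicted label is kept
        for p, inter in zip(row.indices, row.data):
            p = int(p)
            if p == 0 or p in used:
                continue
            union = gt_sizes[g] + pr_sizes[p] - int(inter)
            j = inter / union
            if j > best_j:
                best_p, best_j, best_inter = p, j, int(inter)
        if best_p is None:
            den += gt_sizes[g]
        else:
            used.add(best_p)
            num += best_inter
            den += gt_sizes[g] + pr_sizes[best_p] - best_inter
    for p, size in pr_sizes.items():
        if p not in used:
            den += size
    return num, den


def aji(truth, pred) -> float:
    """Aggregated Jaccard index of a predicted instance map against truth.

    Returns 1.0 when both maps are empty (no nuclei anywhere).
    """
    num, den = aji_parts(truth, pred)
    if den == 0:
        return 1.0
    return num / den


def dataset_aji(truths, preds, mode: str = "mean") -> float:
    """Aggregate AJI over a corpus: per-image mean or pooled accumulation."""
    if mode not in ("mean", "pooled"):
        raise ValueError("mode must be 'mean' or 'pooled'")
    if mode == "mean":
        return float(np.mean([aji(t, p) for t, p in zip(truths, preds)]))
    num = den = 0
    for t, p in zip(truths, preds):
        n, d = aji_parts(t, p)
        num += n
        den += d
    return num / den if den else 1.0


def instances_from_probability(prob, threshold: float = 0.5,
                               min_size: int = 4) -> np.ndarray:
    """Binarize, drop components below ``min_size`` pixels, label 8-connected
    components 1..L in raster order of their first pixel."""
    prob = np.asarray(prob)
    binary = prob >= threshold
    lab = cc_label(binary, connectivity=2)
    if lab.max() == 0:
        return np.zeros_like(lab, dtype=np.int32)
    flat = lab.ravel()
    sizes = np.bincount(flat)
    keep = set(int(v) for v in np.flatnonzero(sizes >= min_size) if v > 0)
    # order surviving components by their first pixel in raster scan
    vals, first_idx = np.unique(flat, return_index=True)
    order = sorted((int(fi), int(v)) for v, fi in zip(vals, first_idx) if int(v) in keep)
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    for new, (_, old) in enumerate(order, start=1):
        lut[old] = new
    return lut[lab]


def evaluate_pair(truth_labels, pred_labels) -> MetricsReport:
    """All metrics for one image from two instance label maps."""
    truth_labels = _check_labels(truth_labels)
    pred_labels = _check_labels(pred_labels)
    tb, pb = truth_labels > 0, pred_labels > 0
    precision, recall, f1 = pixel_prf(pb, tb)
    return MetricsReport(
        dsc=dice(pb, tb),
        f1=f1,
        precision=precision,
        recall=recall,
        aji=aji(truth_labels, pred_labels),
    )


def metrics_table(reports: dict) -> pd.DataFrame:
    """Per-image rows plus an unweighted-mean 'aggregate' row.

    ``reports`` maps image names to :class:`MetricsReport`; columns are
    exactly dsc, f1, recall, precision, aji.
    """
    rows = {name: asdict(r) for name, r in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[CSV_COLUMNS]
    df.loc["aggregate"] = df.mean(axis=0)
    df.index.name = "image"
    return df
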