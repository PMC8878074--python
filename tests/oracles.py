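"""Independent brute-force oracles used across the test suite.

Everything here is written with explicit Python loops and no reuse of the
package's vectorized code paths, so agreement between the two is evidence
of correctness rather than tautology.
"""

from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# blur pooling
# ---------------------------------------------------------------------------

def binomial_kernel(size):
    row = [comb(size - 1, k) for k in range(size)]
    w = np.array([[a * b for b in row] for a in row], dtype=float)
    return w / w.sum()


def reflect_index(i, n):
    """Mirror an out-of-range index back into [0, n) (no edge repeat)."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i
        if i >= n:
            i = 2 * (n - 1) - i
    return i


def blur_filter_loops(x, size):
    """Stride-1 correlation with the binomial kernel, reflect padding."""
    w = binomial_kernel(size)
    lo = (size - 1) // 2
    B, C, H, W = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(B):
        for c in range(C):
            for y in range(H):
                for xx in range(W):
                    acc = 0.0
                    for i in range(size):
                        for j in range(size):
                            yy = reflect_index(y + i - lo, H)
                            xj = reflect_index(xx + j - lo, W)
                            acc += w[i, j] * x[b, c, yy, xj]
                    out[b, c, y, xx] = acc
    return out


def dense_max_loops(x):
    """2x2 stride-1 max, bottom/right edge-padded so the size is kept."""
    B, C, H, W = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(B):
        for c in range(C):
            for y in range(H):
                for xx in range(W):
                    vals = []
                    for dy in (0, 1):
                        for dx in (0, 1):
                            vals.append(x[b, c, min(y + dy, H - 1), min(xx + dx, W - 1)])
                    out[b, c, y, xx] = max(vals)
    return out


def blur_downsample_loops(x, size, stride):
    return blur_filter_loops(x, size)[:, :, ::stride, ::stride]


def blur_max_pool_loops(x, size, stride=2):
    return blur_downsample_loops(dense_max_loops(x), size, stride)


def repeated_blur_pool_to_scalar(x2d, size):
    """Channel descriptor: pad to the next power of two, pool to 1x1."""
    H, W = x2d.shape
    p = 1
    while p < max(H, W):
        p *= 2
    if (H, W) != (p, p):
        padded = np.zeros((p, p))
        for y in range(p):
            for xx in range(p):
                padded[y, xx] = x2d[reflect_index(y, H) if y >= H else y,
                                    reflect_index(xx, W) if xx >= W else xx]
        x2d = padded
    arr = x2d[None, None]
    while arr.shape[-1] > 1 or arr.shape[-2] > 1:
        arr = blur_max_pool_loops(arr, size, 2)
    return float(arr[0, 0, 0, 0])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pixel_counts_loops(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def aji_loops(truth, pred):
    """Aggregated Jaccard index straight from its definition.

    Pairwise Jaccard tables, greedy max-Jaccard matching in ascending
    ground-truth order with one-to-one consumption (ties to the lowest
    predicted label), unmatched ground truth and predictions added to the
    denominator.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    g_labels = sorted(set(truth.ravel().tolist()) - {0})
    p_labels = sorted(set(pred.ravel().tolist()) - {0})
    g_masks = {g: truth == g for g in g_labels}
    p_masks = {p: pred == p for p in p_labels}
    used = set()
    num = den = 0
    for g in g_labels:
        best_p, best_j = None, -1.0
        for p in p_labels:
            if p in used:
                continue
            inter = int((g_masks[g] & p_masks[p]).sum())
            if inter == 0:
                continue
            union = int((g_masks[g] | p_masks[p]).sum())
            j = inter / union
            if j > best_j:
                best_p, best_j = p, j
        if best_p is None:
            den += int(g_masks[g].sum())
        else:
            used.add(best_p)
            num += int((g_masks[g] & p_masks[best_p]).sum())
            den += int((g_masks[g] | p_masks[best_p]).sum())
    for p in p_labels:
        if p not in used:
            den += int(p_masks[p].sum())
    if den == 0:
        return 1.0
    return num / den


def flood_fill_count(binary):
    """Number of 8-connected components, by explicit BFS flood fill."""
    binary = np.asarray(binary).astype(bool)
    H, W = binary.shape
    seen = np.zeros_like(binary)
    count = 0
    for y in range(H):
        for x in range(W):
            if binary[y, x] and not seen[y, x]:
                count += 1
                stack = [(y, x)]
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < H and 0 <= nx < W and binary[ny, nx] \
                                    and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
    return count


def random_label_map(rng, size=32, max_instances=5):
    """Random instance map of non-overlapping rectangles/disks, labels 1..k."""
    labels = np.zeros((size, size), dtype=np.int32)
    n = int(rng.integers(0, max_instances + 1))
    placed = 0
    for _ in range(n):
        for _try in range(20):
            h = int(rng.integers(2, size // 3))
            w = int(rng.integers(2, size // 3))
            y = int(rng.integers(0, size - h))
            x = int(rng.integers(0, size - w))
            region = labels[y:y + h, x:x + w]
            if (region == 0).all():
                placed += 1
                region[:] = placed
                break
    return labels
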