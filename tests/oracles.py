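"""Independent reference implementations used as test oracles.

Deliberately naive: pixel counting, exhaustive scans and enumeration,
written without reuse of the package's own code paths.
"""

import numpy as np


def iou_by_rasterization(box_a, box_b, scale: int = 1) -> float:
    """IoU by literally counting pixels on a raster grid.

    Boxes are (x, y, w, h) with non-negative integer coordinates.
    """
    ax, ay, aw, ah = (int(v * scale) for v in box_a)
    bx, by, bw, bh = (int(v * scale) for v in box_b)
    W = max(ax + aw, bx + bw) + 1
    H = max(ay + ah, by + bh) + 1
    grid_a = np.zeros((H, W), dtype=bool)
    grid_b = np.zeros((H, W), dtype=bool)
    grid_a[ay:ay + ah, ax:ax + aw] = True
    grid_b[by:by + bh, bx:bx + bw] = True
    inter = np.logical_and(grid_a, grid_b).sum()
    union = np.logical_or(grid_a, grid_b).sum()
    return inter / union


def laplacian_variance_reference(L: np.ndarray) -> float:
    """Sharpness score via an explicit loop-free shift-and-add Laplacian
    (reflect border), variance over the interior."""
    padded = np.pad(L, 1, mode="reflect")
    resp = (padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2]
            + padded[1:-1, 2:] - 4 * L)
    return float(resp[1:-1, 1:-1].var())


def segment_reference(values, calm_threshold, min_length):
    """Exhaustive O(n^2)-style reference for calm/oscillation segmentation.

    Builds maximal threshold runs by scanning, then repeatedly absorbs
    the shortest run below min_length into its longer neighbour
    (ties: preceding), re-deriving the run list from a per-frame label
    array after every merge.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return []
    labels = np.where(values >= calm_threshold, "oscillation", "calm")

    def runs_of(lab):
        out = []
        i = 0
        while i < n:
            j = i
            while j < n and lab[j] == lab[i]:
                j += 1
            out.append((lab[i], i, j))
            i = j
        return out

    while True:
        runs = runs_of(labels)
        if len(runs) <= 1:
            break
        lengths = [e - s for _, s, e in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_length]
        if not short:
            break
        i = min(short, key=lambda j: (lengths[j], j))
        left = lengths[i - 1] if i > 0 else -1
        right = lengths[i + 1] if i + 1 < len(runs) else -1
        target = i - 1 if left >= right else i + 1
        kind, s, e = runs[i]
        labels[s:e] = runs[target][0]
    return [(k, s, e) for k, s, e in runs_of(labels)]


def average_precision_reference(tp_flags, n_gt):
    """AP by explicit enumeration of the PR curve from an ordered TP/FP
    sequence, 101-point interpolation evaluated pointwise."""
    tp_flags = list(tp_flags)
    precisions, recalls = [], []
    tp = fp = 0
    for flag in tp_flags:
        if flag:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    total = 0.0
    for k in range(101):
        r = k / 100
        best = 0.0
        for p, rr in zip(precisions, recalls):
            if rr >= r and p > best:
                best = p
        total += best
    return total / 101
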