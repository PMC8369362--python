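"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own implementations: erosion is a
loop over structuring-element offsets, component labeling is a flood fill,
NMS is a from-scratch fixed-point rescanner, and FROC curves come from an
exhaustive per-threshold recount.
"""

from __future__ import annotations

import math


def brute_erosion(image, radius: int):
    """Binary erosion of ``image > 0`` by a disk, via explicit offset loops."""
    import numpy as np

    img = np.asarray(image) > 0
    h, w = img.shape
    offsets = [(di, dj)
               for di in range(-radius, radius + 1)
               for dj in range(-radius, radius + 1)
               if di * di + dj * dj <= radius * radius]
    out = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            ok = True
            for di, dj in offsets:
                y, x = i + di, j + dj
                if not (0 <= y < h and 0 <= x < w) or not img[y, x]:
                    ok = False
                    break
            out[i, j] = ok
    return out


def brute_largest_component(mask):
    """Largest 8-connected component by breadth-first flood fill."""
    import numpy as np

    mask = np.asarray(mask) > 0
    h, w = mask.shape
    seen = np.zeros_like(mask)
    best: list = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            comp = []
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            if len(comp) > len(best):
                best = comp
    out = np.zeros_like(mask)
    for y, x in best:
        out[y, x] = True
    return out


# ---------------------------------------------------------------------------
# NMS oracle: plain tuples (x, y, w, h, z, score)


def _tuple_iou(a, b) -> float:
    ax, ay, aw, ah = a[:4]
    bx, by, bw, bh = b[:4]
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def brute_merge_nms(boxes, ratio_gate: float = 10.0, iou_gate: float = 0.5):
    """Fixed-point merge: highest-IoU qualifying pair first (ties by higher
    max score), merged box = higher-scoring member with score = max."""
    boxes = [tuple(b) for b in boxes]
    while True:
        candidates = []
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                si, sj = boxes[i][5], boxes[j][5]
                ratio = max(si, sj) / min(si, sj)
                ov = _tuple_iou(boxes[i], boxes[j])
                if ratio < ratio_gate and ov > iou_gate:
                    candidates.append((ov, max(si, sj), i, j))
        if not candidates:
            return boxes
        candidates.sort(reverse=True)
        _, _, i, j = candidates[0]
        winner = boxes[i] if boxes[i][5] >= boxes[j][5] else boxes[j]
        merged = winner[:5] + (max(boxes[i][5], boxes[j][5]),)
        boxes = [b for k, b in enumerate(boxes) if k not in (i, j)] + [merged]


# ---------------------------------------------------------------------------
# FROC oracle: predictions/gts as plain dicts of tuples, lesions assumed to
# have pairwise-disjoint eligibility regions (so matching is per-lesion)


def _matches(pred, gt, n_slices, floor=100.0, z_fraction=0.25) -> bool:
    px, py = pred[0] + pred[2] / 2.0, pred[1] + pred[3] / 2.0
    gx, gy = gt[0] + gt[2] / 2.0, gt[1] + gt[3] / 2.0
    diag = math.hypot(gt[2], gt[3])
    if math.hypot(px - gx, py - gy) >= max(diag / 2.0, floor):
        return False
    r = round(z_fraction * n_slices)
    lo, hi = max(0, gt[4] - r), min(n_slices - 1, gt[4] + r)
    return lo <= pred[4] <= hi


def brute_froc(predictions, ground_truths, n_slices, floor=100.0):
    """Exhaustive threshold-by-threshold curve for disjoint-eligibility GTs.

    predictions: key -> [(x, y, w, h, z, score)]
    ground_truths: key -> [(x, y, w, h, center_slice)]
    Returns sorted (fp_per_volume, sensitivity) with best-per-fp collapsing.
    """
    scores = sorted({b[5] for bs in predictions.values() for b in bs}, reverse=True)
    n_volumes = len(predictions)
    total_gt = sum(len(v) for v in ground_truths.values())
    points = []
    for t in scores:
        tp = 0
        fp = 0
        for key, boxes in predictions.items():
            kept = [b for b in boxes if b[5] >= t]
            used = 0
            for gt in ground_truths.get(key, []):
                if any(_matches(b, gt, n_slices[key], floor) for b in kept):
                    tp += 1
                    used += 1
            fp += len(kept) - used
        points.append((fp / n_volumes, tp / total_gt))
    points.sort()
    out = []
    best = 0.0
    for fp_rate, s in points:
        best = max(best, s)
        if out and out[-1][0] == fp_rate:
            out[-1] = (fp_rate, best)
        else:
            out.append((fp_rate, best))
    return out


def brute_froc_breast(predictions, ground_truths, n_slices, views, floor=100.0):
    """Breast-level exhaustive curve; ``views`` maps key -> view string."""
    scores = sorted({b[5] for bs in predictions.values() for b in bs}, reverse=True)
    n_volumes = len(predictions)
    breasts = {(k[0], k[1], views[k][0]) for k, v in ground_truths.items() if v}
    points = []
    for t in scores:
        fp = 0
        detected = set()
        for key, boxes in predictions.items():
            kept = [b for b in boxes if b[5] >= t]
            used = 0
            for gt in ground_truths.get(key, []):
                if any(_matches(b, gt, n_slices[key], floor) for b in kept):
                    used += 1
                    detected.add((key[0], key[1], views[key][0]))
            fp += len(kept) - used
        points.append((fp / n_volumes, len(detected & breasts) / len(breasts)))
    points.sort()
    out = []
    best = 0.0
    for fp_rate, s in points:
        best = max(best, s)
        if out and out[-1][0] == fp_rate:
            out[-1] = (fp_rate, best)
        else:
            out.append((fp_rate, best))
    return out
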