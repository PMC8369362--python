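"""Volume-level inference and post-processing.

A volume is split into two slice halves; per-slice output grids within each
half are averaged elementwise, decoded, then all boxes pass the breast-region
filter and merge-based non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detector_core import DetectionGrid, Detector, decode_predictions
from .io_formats import PredictedBox, Volume
from .preprocess import BreastMask

__all__ = [
    "VolumePredictions", "pad_to_grid", "predict_volume",
    "filter_outside_breast", "iou", "merge_nms",
    "SCORE_RATIO_GATE", "IOU_GATE", "DEFAULT_DECODE_THRESHOLD",
]

CELL = 96
SCORE_RATIO_GATE = 10.0   # merge only if max/min score < 10
IOU_GATE = 0.5            # ... and IoU > 0.5
DEFAULT_DECODE_THRESHOLD = 0.05


@dataclass
class VolumePredictions:
    patient_id: str
    study_id: str
    view: object
    boxes: list


def pad_to_grid(slice_: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad bottom/right to the next multiple of the 96-px cell size.

    Returns the padded slice and (pad_rows, pad_cols); decoded boxes need no
    coordinate shift (padding is bottom/right) but must be clipped back.
    """
    h, w = slice_.shape
    ph = (-h) % CELL
    pw = (-w) % CELL
    if ph == 0 and pw == 0:
        return slice_, (0, 0)
    return np.pad(slice_, ((0, ph), (0, pw))), (ph, pw)


def iou(a: PredictedBox, b: PredictedBox) -> float:
    """2-D intersection over union on half-open boxes."""
    ix = max(0.0, min(a.x + a.width, b.x + b.width) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.height, b.y + b.height) - max(a.y, b.y))
    inter = ix * iy
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


def merge_nms(boxes: list[PredictedBox]) -> list[PredictedBox]:
    """Merge pairs with score ratio < 10 and IoU > 0.5, to a fixed point.

    At each step the qualifying pair with the highest IoU is merged (ties:
    higher max score first); the merged box keeps the higher-scoring member's
    geometry and z, with score = max of the pair.
    """
    for b in boxes:
        if b.score <= 0:
            raise ValueError("merge_nms requires strictly positive scores")
    boxes = list(boxes)
    while True:
        best = None
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                si, sj = boxes[i].score, boxes[j].score
                if max(si, sj) / min(si, sj) >= SCORE_RATIO_GATE:
                    continue
                ov = iou(boxes[i], boxes[j])
                if ov <= IOU_GATE:
                    continue
                key = (ov, max(si, sj))
                if best is None or key > best[0]:
                    best = (key, i, j)
        if best is None:
            return boxes
        _, i, j = best
        keep = boxes[i] if boxes[i].score >= boxes[j].score else boxes[j]
        merged = replace(keep, score=max(boxes[i].score, boxes[j].score))
        boxes = [b for k, b in enumerate(boxes) if k not in (i, j)]
        boxes.append(merged)


def filter_outside_breast(boxes: list[PredictedBox], masks: list[BreastMask]) -> list[PredictedBox]:
    """Keep a box iff at least half of its pixels lie in the breast mask at its z."""
    kept = []
    for b in boxes:
        if not (0 <= b.z < len(masks)):
            raise ValueError(f"no breast mask for slice z={b.z}")
        mask = masks[b.z].mask
        h, w = mask.shape
        x0, x1 = int(np.floor(b.x)), int(np.ceil(b.x + b.width))
        y0, y1 = int(np.floor(b.y)), int(np.ceil(b.y + b.height))
        area = (x1 - x0) * (y1 - y0)
        cx0, cx1 = max(0, x0), min(w, x1)
        cy0, cy1 = max(0, y0), min(h, y1)
        inside = int(mask[cy0:cy1, cx0:cx1].sum()) if (cx1 > cx0 and cy1 > cy0) else 0
        if area > 0 and inside >= 0.5 * area:
            kept.append(b)
    return kept


def _average_grids(grids: list[DetectionGrid]) -> DetectionGrid:
    conf = np.mean([g.confidence for g in grids], axis=0)
    reg = np.mean([g.regression for g in grids], axis=0)
    return DetectionGrid(confidence=conf, regression=reg)


def predict_volume(
    detector: Detector,
    volume: Volume,
    masks: list[BreastMask],
    threshold: float = DEFAULT_DECODE_THRESHOLD,
    batch_size: int = 8,
) -> VolumePredictions:
    """Full-volume inference on a preprocessed volume.

    Slices are padded to the grid, run through the detector, and the output
    grids of each half-volume ([0, N/2) and [N/2, N)) are averaged before
    decoding.  Each decoded box gets z = the middle slice of its half; boxes
    then pass the breast filter and merge NMS.
    """
    n = volume.n_slices
    if n == 0:
        raise ValueError("empty volume")
    padded = np.stack([pad_to_grid(volume.pixels[k])[0] for k in range(n)])
    grids: list[DetectionGrid] = []
    for start in range(0, n, batch_size):
        grids.extend(detector.forward(padded[start:start + batch_size]))

    h, w = volume.pixels.shape[1:]
    halves = [(0, n // 2), (n // 2, n)] if n > 1 else [(0, 1)]
    boxes: list[PredictedBox] = []
    for lo, hi in halves:
        if hi <= lo:
            continue
        avg = _average_grids(grids[lo:hi])
        mid = (lo + hi - 1) // 2
        for b in decode_predictions(avg, threshold):
            # clip back into the unpadded slice extent
            x = float(np.clip(b.x, 0, w - 1))
            y = float(np.clip(b.y, 0, h - 1))
            bw = max(1.0, min(b.width, w - x))
            bh = max(1.0, min(b.height, h - y))
            boxes.append(replace(
                b, x=x, y=y, width=bw, height=bh, z=mid,
                patient_id=volume.patient_id, study_id=volume.study_id,
                view=volume.view,
            ))
    boxes = filter_outside_breast(boxes, masks)
    boxes = merge_nms(boxes)
    return VolumePredictions(patient_id=volume.patient_id, study_id=volume.study_id,
                             view=volume.view, boxes=boxes)
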