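"""Training protocol: positive-slice sampling, crop construction, Adam
optimization, per-epoch validation at 2 FP/slice, early stopping, and
model selection across loss functions by volume-level FROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .detector_core import Detector, decode_predictions
from .froc_eval import MatchCriteria, froc_slice, froc_volume, sensitivity_at
from .ground_truth import CELL, GroundTruthBox3D, TargetGrid, encode_target_grid
from .inference_post import merge_nms, predict_volume
from .io_formats import Volume
from .losses import (
    LossConfig, LossKind, localization_mse_and_grad, objectness_loss_and_grad,
    prevalence_weights,
)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainingExample", "Adam", "sample_training_example",
           "fixed_validation_example", "train", "select_model"]

VALIDATION_FP_PER_SLICE = 2.0
SELECTION_FP_PER_VOLUME = 2.0


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 25
    crop: tuple[int, int] = (1056, 672)  # (width, height) in preprocessed px
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    decode_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        w, h = self.crop
        if w % CELL or h % CELL:
            raise ValueError(f"crop dims must be multiples of {CELL}")

    @property
    def crop_shape(self) -> tuple[int, int]:
        """(rows, cols)."""
        return (self.crop[1], self.crop[0])


@dataclass
class TrainingExample:
    """One positive lesion within a preprocessed volume.

    ``boxes`` holds every lesion of the volume (for the target grid);
    ``primary`` indexes the lesion this example is sampled around.
    """

    volume: Volume
    boxes: list[GroundTruthBox3D]
    primary: int = 0


class Adam:
    """Adam over the detector's (param, grad) pairs; framework defaults."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _extract_crop(pixels: np.ndarray, y0: int, x0: int, shape: tuple[int, int]) -> np.ndarray:
    """Crop with zero padding when the image is smaller than the window."""
    ch, cw = shape
    h, w = pixels.shape
    out = np.zeros(shape, dtype=np.float32)
    ys, xs = max(0, y0), max(0, x0)
    ye, xe = min(h, y0 + ch), min(w, x0 + cw)
    if ye > ys and xe > xs:
        out[ys - y0:ye - y0, xs - x0:xe - x0] = pixels[ys:ye, xs:xe]
    return out


def _offset_range(lo_edge: float, hi_edge: float, crop: int, limit: int) -> tuple[int, int]:
    """Integer crop offsets that keep [lo_edge, hi_edge) fully inside the crop,
    clipped so the crop stays within [0, limit) where possible."""
    lo = int(np.ceil(hi_edge)) - crop
    hi = int(np.floor(lo_edge))
    lo = max(lo, 0) if limit >= crop else lo
    hi = min(hi, limit - crop) if limit >= crop else hi
    if lo > hi:  # box does not fit: center the crop on the box
        mid = int(round((lo_edge + hi_edge) / 2.0)) - crop // 2
        return mid, mid
    return lo, hi


def _grid_targets(
    example: TrainingExample, z: int, y0: int, x0: int, shape: tuple[int, int]
) -> TargetGrid:
    boxes = []
    for gt in example.boxes:
        if gt.slice_lo <= z <= gt.slice_hi:
            boxes.append((gt.x - x0, gt.y - y0, gt.width, gt.height))
    return encode_target_grid(boxes, shape)


def sample_training_example(
    example: TrainingExample,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, TargetGrid]:
    """Random positive slice + random crop fully containing the primary box."""
    gt = example.boxes[example.primary]
    vol = example.volume
    z = int(rng.integers(gt.slice_lo, gt.slice_hi + 1))
    ch, cw = config.crop_shape
    h, w = vol.pixels.shape[1:]
    if gt.width > cw or gt.height > ch:
        logger.warning("ground-truth box %gx%g larger than crop %dx%d; center-cropping",
                       gt.width, gt.height, cw, ch)
    ylo, yhi = _offset_range(gt.y, gt.y + gt.height, ch, h)
    xlo, xhi = _offset_range(gt.x, gt.x + gt.width, cw, w)
    y0 = int(rng.integers(ylo, yhi + 1))
    x0 = int(rng.integers(xlo, xhi + 1))
    crop = _extract_crop(vol.pixels[z], y0, x0, (ch, cw))
    return crop, _grid_targets(example, z, y0, x0, (ch, cw))


def fixed_validation_example(
    example: TrainingExample,
    config: TrainConfig,
) -> tuple[np.ndarray, TargetGrid]:
    """Deterministic: middle slice of the (halved) validation span, crop
    centered on the box and clipped to the image."""
    gt = example.boxes[example.primary]
    vol = example.volume
    z = (gt.slice_lo + gt.slice_hi) // 2
    ch, cw = config.crop_shape
    h, w = vol.pixels.shape[1:]
    cx, cy = gt.center
    y0 = int(round(cy)) - ch // 2
    x0 = int(round(cx)) - cw // 2
    if h >= ch:
        y0 = min(max(y0, 0), h - ch)
    if w >= cw:
        x0 = min(max(x0, 0), w - cw)
    crop = _extract_crop(vol.pixels[z], y0, x0, (ch, cw))
    return crop, _grid_targets(example, z, y0, x0, (ch, cw))


def _loss_with_prevalence(config: TrainConfig, examples: list[TrainingExample]) -> LossConfig:
    loss = config.loss
    if loss.kind is not LossKind.WEIGHTED_BCE or loss.w_pos is not None:
        return loss
    ch, cw = config.crop_shape
    cells = (ch // CELL) * (cw // CELL)
    n_pos = sum(len(e.boxes) for e in examples)
    n_total = cells * len(examples)
    w_pos, w_neg = prevalence_weights(max(1, n_pos), max(1, n_total - n_pos))
    return replace(loss, w_pos=w_pos, w_neg=w_neg)


def _validation_metric(
    detector: Detector,
    val_crops: list[tuple[np.ndarray, TargetGrid]],
    config: TrainConfig,
    criteria: MatchCriteria,
) -> float:
    """Sensitivity at 2 FP per slice over the fixed validation crops (2-D)."""
    from .ground_truth import decode_target_grid
    from .io_formats import LesionClass, LesionType

    preds, gts = [], []
    for crop, target in val_crops:
        grid = detector.forward(crop[None])[0]
        boxes = merge_nms(decode_predictions(grid, config.decode_threshold))
        preds.append(boxes)
        gt_list = [
            GroundTruthBox3D(x=x, y=y, width=w, height=h, center_slice=0,
                             slice_lo=0, slice_hi=0,
                             lesion_class=LesionClass.BENIGN, lesion_type=LesionType.MASS)
            for (x, y, w, h) in decode_target_grid(target)
        ]
        gts.append(gt_list)
    if not any(gts):
        return 0.0
    curve = froc_slice(preds, gts, criteria)
    return sensitivity_at(curve, VALIDATION_FP_PER_SLICE)


def train(
    detector: Detector,
    train_examples: list[TrainingExample],
    val_examples: list[TrainingExample],
    config: TrainConfig,
    criteria: MatchCriteria = MatchCriteria(),
) -> tuple[Detector, list[dict]]:
    """One epoch = one shuffled pass over positive examples; after each epoch
    the model is scored on fixed validation crops and the best is kept.
    Stops after ``patience`` epochs without improvement."""
    if not train_examples:
        raise ValueError("training requires at least one positive example")
    loss_cfg = _loss_with_prevalence(config, train_examples)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(detector.params(), lr=config.learning_rate)
    val_crops = [fixed_validation_example(e, config) for e in val_examples]

    best_metric = -np.inf
    best_params = None
    best_epoch = -1
    history: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_examples))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            crops, targets = [], []
            for k in batch_idx:
                crop, target = sample_training_example(train_examples[k], config, rng)
                crops.append(crop)
                targets.append(target)
            batch = np.stack(crops)
            obj = np.stack([t.objectness for t in targets])
            reg = np.stack([t.regression for t in targets])
            mask = obj > 0.5

            detector.zero_grad()
            grids = detector.forward(batch, train=True)
            conf = np.stack([g.confidence for g in grids])
            pred_reg = np.stack([g.regression for g in grids])

            obj_loss, d_conf = objectness_loss_and_grad(conf, obj, loss_cfg)
            loc_loss, d_reg = localization_mse_and_grad(
                np.moveaxis(pred_reg, 1, 0), np.moveaxis(reg, 1, 0), mask)
            d_reg = np.moveaxis(d_reg, 0, 1) * loss_cfg.loc_weight
            detector.backward(d_conf.astype(np.float32), d_reg.astype(np.float32))
            optimizer.step()
            epoch_loss += obj_loss + loss_cfg.loc_weight * loc_loss
            n_batches += 1

        metric = _validation_metric(detector, val_crops, config, criteria) \
            if val_crops else 0.0
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(1, n_batches),
            "val_sensitivity_2fp_slice": metric,
        })
        if metric > best_metric:
            best_metric = metric
            best_epoch = epoch
            best_params = [p.copy() for p, _ in detector.params()]
        elif metric == best_metric and best_params is not None:
            # tie: prefer the most recent weights (lower training loss);
            # does not reset the early-stopping counter
            best_params = [p.copy() for p, _ in detector.params()]
        logger.info("epoch %d loss %.5f val %.3f", epoch,
                    history[-1]["train_loss"], metric)
        if epoch - best_epoch >= config.patience:
            break

    if best_params is not None:
        for (p, _), saved in zip(detector.params(), best_params):
            p[...] = saved
    return detector, history


def select_model(
    candidates: list[tuple[str, Detector]],
    val_volumes: list[tuple[Volume, list]],
    ground_truths: dict,
    n_slices: dict,
    criteria: MatchCriteria = MatchCriteria(),
    fp_rate: float = SELECTION_FP_PER_VOLUME,
) -> tuple[str, Detector]:
    """Full 3-D inference + volume FROC per candidate; returns the candidate
    with the highest sensitivity at ``fp_rate`` FP/volume.  Ties break toward
    the lower FP rate at which that sensitivity is reached, then list order."""
    if not candidates:
        raise ValueError("no candidates to select from")
    scored = []
    for order, (name, detector) in enumerate(candidates):
        predictions = {}
        for volume, masks in val_volumes:
            vp = predict_volume(detector, volume, masks)
            predictions[(volume.patient_id, volume.study_id, volume.view)] = vp.boxes
        curve = froc_volume(predictions, ground_truths, n_slices, criteria)
        sens = sensitivity_at(curve, fp_rate)
        fp_needed = next((fp for fp, s in curve.points if s >= sens), 0.0)
        scored.append((-sens, fp_needed, order, name, detector))
    scored.sort()
    _, _, _, name, detector = scored[0]
    return name, detector
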