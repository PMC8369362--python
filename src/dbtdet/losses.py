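"""Objectness losses for the lesion/background class imbalance, plus the
MSE localization loss.  Each loss returns elementwise values; the *_grad
variants also return d(loss)/d(probability) for the numpy training loop.

Probabilities are clamped to [1e-7, 1 - 1e-7] before taking logs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossKind", "LossConfig", "bce", "weighted_bce", "focal", "reduced_focal",
    "localization_mse", "objectness_loss_and_grad", "localization_mse_and_grad",
    "prevalence_weights",
]

EPS = 1e-7


class LossKind(str, enum.Enum):
    BCE = "bce"
    WEIGHTED_BCE = "weighted_bce"
    FOCAL = "focal"
    REDUCED_FOCAL = "reduced_focal"


@dataclass(frozen=True)
class LossConfig:
    kind: LossKind = LossKind.FOCAL
    alpha: float = 0.25
    gamma: float = 2.0
    reduced_threshold: float = 0.5
    # weighted_bce weights; None means derive from prevalence at training time
    w_pos: float | None = None
    w_neg: float | None = None
    loc_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.reduced_threshold < 1.0):
            raise ValueError("reduced_threshold must be in (0, 1)")
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be >= 0")


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)


def bce(p, y):
    """-[y ln p + (1 - y) ln(1 - p)], elementwise."""
    p = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def weighted_bce(p, y, w_pos: float, w_neg: float):
    """Class-weighted cross-entropy: w_pos on the y-term, w_neg on the (1-y)-term."""
    if w_pos <= 0 or w_neg <= 0:
        raise ValueError("class weights must be positive")
    p = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    return -(w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log(1.0 - p))


def prevalence_weights(n_pos: int, n_neg: int) -> tuple[float, float]:
    """Inverse-class-frequency weights normalized so w_pos + w_neg == 2."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("need at least one example of each class")
    inv_pos, inv_neg = 1.0 / n_pos, 1.0 / n_neg
    scale = 2.0 / (inv_pos + inv_neg)
    return inv_pos * scale, inv_neg * scale


def focal(p, y, alpha: float = 0.25, gamma: float = 2.0):
    """-alpha (1 - p_t)^gamma ln p_t with p_t the true-class probability."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    p = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    pt = y * p + (1.0 - y) * (1.0 - p)
    return -alpha * (1.0 - pt) ** gamma * np.log(pt)


def reduced_focal(p, y, gamma: float = 2.0, threshold: float = 0.5):
    """Cross-entropy below ``threshold`` true-class probability; scaled down by
    ((1 - p_t) / threshold)^gamma above it.  Continuous at the threshold."""
    p = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    pt = y * p + (1.0 - y) * (1.0 - p)
    base = -np.log(pt)
    factor = np.where(pt < threshold, 1.0, ((1.0 - pt) / threshold) ** gamma)
    return factor * base


def localization_mse(pred_reg, target_reg, positive_mask):
    """MSE over the 4 regression channels at positive cells; 0 with none."""
    mask = np.asarray(positive_mask, dtype=bool)
    if not mask.any():
        return 0.0
    diff = np.asarray(pred_reg, dtype=np.float64) - np.asarray(target_reg, dtype=np.float64)
    return float((diff[:, mask] ** 2).mean())


# ---------------------------------------------------------------------------
# Value-and-gradient forms used by the training loop.  Gradients are with
# respect to the predicted probability p (the network's sigmoid output).


def _grad_pt(p, y, dl_dpt):
    """Chain d/dp_t back to d/dp: p_t = p for y=1, 1-p for y=0."""
    y = np.asarray(y, dtype=np.float64)
    return dl_dpt * (2.0 * y - 1.0)


def objectness_loss_and_grad(p, y, config: LossConfig):
    """Mean objectness loss over all cells and its gradient wrt p."""
    p = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    pt = y * p + (1.0 - y) * (1.0 - p)
    n = p.size
    kind = config.kind
    if kind is LossKind.BCE:
        loss = -np.log(pt)
        dl_dpt = -1.0 / pt
    elif kind is LossKind.WEIGHTED_BCE:
        w_pos = config.w_pos if config.w_pos is not None else 1.0
        w_neg = config.w_neg if config.w_neg is not None else 1.0
        w = y * w_pos + (1.0 - y) * w_neg
        loss = -w * np.log(pt)
        dl_dpt = -w / pt
    elif kind is LossKind.FOCAL:
        a, g = config.alpha, config.gamma
        one_m = 1.0 - pt
        loss = -a * one_m ** g * np.log(pt)
        if g == 0:
            dl_dpt = -a / pt
        else:
            dl_dpt = a * (g * one_m ** (g - 1.0) * np.log(pt) - one_m ** g / pt)
    elif kind is LossKind.REDUCED_FOCAL:
        g, th = config.gamma, config.reduced_threshold
        base = -np.log(pt)
        one_m = 1.0 - pt
        factor = np.where(pt < th, 1.0, (one_m / th) ** g)
        loss = factor * base
        if g == 0:
            dl_dpt = -1.0 / pt
        else:
            dfactor = np.where(pt < th, 0.0, -g * one_m ** (g - 1.0) / th ** g)
            dl_dpt = dfactor * base - factor / pt
    else:  # pragma: no cover
        raise ValueError(f"unknown loss kind {kind}")
    grad = _grad_pt(p, y, dl_dpt) / n
    return float(loss.mean()), grad


def localization_mse_and_grad(pred_reg, target_reg, positive_mask):
    """MSE at positive cells and its gradient wrt pred_reg (zero elsewhere)."""
    mask = np.asarray(positive_mask, dtype=bool)
    grad = np.zeros_like(np.asarray(pred_reg, dtype=np.float64))
    if not mask.any():
        return 0.0, grad
    diff = np.asarray(pred_reg, dtype=np.float64) - np.asarray(target_reg, dtype=np.float64)
    n_terms = 4 * int(mask.sum())
    loss = float((diff[:, mask] ** 2).sum() / n_terms)
    grad[:, mask] = 2.0 * diff[:, mask] / n_terms
    return loss, grad
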