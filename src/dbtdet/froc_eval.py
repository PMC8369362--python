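"""FROC analysis with custom true-positive matching at slice, volume, and
breast level, plus patient-level bootstrap confidence intervals.

A prediction matches a lesion when its 2-D center is closer to the lesion
center than max(half the lesion-box diagonal, 100 px) and its center slice
falls inside the lesion's 25%-of-volume slice window.  Matching is greedy by
descending score with one-to-one lesion assignment (nearest eligible lesion
first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ground_truth import GroundTruthBox3D, evaluation_slice_range
from .io_formats import PredictedBox

__all__ = [
    "MatchCriteria", "FrocCurve", "is_true_positive",
    "froc_volume", "froc_breast", "froc_slice",
    "sensitivity_at", "bootstrap_ci",
]


@dataclass(frozen=True)
class MatchCriteria:
    distance_floor: float = 100.0
    diagonal_fraction: float = 0.5
    z_fraction: float = 0.25
    # stricter optional rule: predicted center must also lie inside the GT box
    require_containment: bool = False

    def __post_init__(self) -> None:
        if self.distance_floor <= 0 or self.diagonal_fraction <= 0 or self.z_fraction <= 0:
            raise ValueError("all matching thresholds must be positive")


@dataclass
class FrocCurve:
    """(fp_per_unit, sensitivity) points, sorted by fp rate, plus optional CI."""

    points: list[tuple[float, float]]
    unit: str
    ci_lo: float | None = None
    ci_hi: float | None = None


def _center_distance(pred: PredictedBox, gt: GroundTruthBox3D) -> float:
    (px, py), (gx, gy) = pred.center, gt.center
    return math.hypot(px - gx, py - gy)


def is_true_positive(
    pred: PredictedBox,
    gt: GroundTruthBox3D,
    n_slices: int,
    criteria: MatchCriteria = MatchCriteria(),
) -> bool:
    """Apply the center-distance rule in 2-D and the slice window in z."""
    limit = max(gt.diagonal * criteria.diagonal_fraction, criteria.distance_floor)
    if _center_distance(pred, gt) >= limit:
        return False
    lo, hi = evaluation_slice_range(gt.center_slice, n_slices)
    if not (lo <= pred.z <= hi):
        return False
    if criteria.require_containment:
        px, py = pred.center
        if not (gt.x <= px < gt.x + gt.width and gt.y <= py < gt.y + gt.height):
            return False
    return True


def _match_volume(
    preds: list[PredictedBox],
    gts: list[GroundTruthBox3D],
    n_slices: int,
    criteria: MatchCriteria,
) -> tuple[set[int], int]:
    """Greedy matching of one volume: returns (matched GT indices, FP count)."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    matched: set[int] = set()
    n_fp = 0
    for i in order:
        eligible = [
            (g, _center_distance(preds[i], gts[g]))
            for g in range(len(gts))
            if g not in matched and is_true_positive(preds[i], gts[g], n_slices, criteria)
        ]
        if eligible:
            matched.add(min(eligible, key=lambda t: t[1])[0])
        else:
            n_fp += 1
    return matched, n_fp


def _sweep(
    predictions: dict,
    ground_truths: dict,
    n_slices: dict,
    criteria: MatchCriteria,
):
    """Yield (threshold, matched-per-volume dict, total FP) over descending scores."""
    scores = sorted({b.score for boxes in predictions.values() for b in boxes},
                    reverse=True)
    for t in scores:
        total_fp = 0
        matched = {}
        for key, boxes in predictions.items():
            kept = [b for b in boxes if b.score >= t]
            m, fp = _match_volume(kept, ground_truths.get(key, []),
                                  n_slices[key], criteria)
            matched[key] = m
            total_fp += fp
        yield t, matched, total_fp


def _finalize(points: list[tuple[float, float]], unit: str) -> FrocCurve:
    points = sorted(points)
    # keep the best sensitivity at each fp rate and enforce monotonicity
    out: list[tuple[float, float]] = []
    best = 0.0
    for fp, s in points:
        best = max(best, s)
        if out and out[-1][0] == fp:
            out[-1] = (fp, best)
        else:
            out.append((fp, best))
    return FrocCurve(points=out, unit=unit)


def froc_volume(
    predictions: dict,
    ground_truths: dict,
    n_slices: dict,
    criteria: MatchCriteria = MatchCriteria(),
) -> FrocCurve:
    """Volume-based FROC: lesion sensitivity vs false positives per volume.

    ``predictions`` maps a volume key (patient, study, view) to its box list
    and must cover every volume in the evaluation set, including lesion-free
    ones (they count in the FP denominator).
    """
    missing = [k for k in ground_truths if k not in predictions]
    if missing:
        raise ValueError(f"annotated volumes without prediction entries: {missing}")
    n_volumes = len(predictions)
    total_gt = sum(len(v) for v in ground_truths.values())
    if n_volumes == 0 or total_gt == 0:
        raise ValueError("need at least one volume and one ground-truth lesion")
    points = [
        (fp / n_volumes, sum(len(m) for m in matched.values()) / total_gt)
        for _, matched, fp in _sweep(predictions, ground_truths, n_slices, criteria)
    ]
    if not points:
        points = [(0.0, 0.0)]
    return _finalize(points, unit="volume")


def _breast_key(volume_key) -> tuple:
    patient, study, view = volume_key
    lat = str(getattr(view, "value", view))[0].upper()
    if lat not in ("L", "R"):
        raise ValueError(f"cannot parse laterality from view {view!r}")
    return (patient, study, lat)


def froc_breast(
    predictions: dict,
    ground_truths: dict,
    n_slices: dict,
    criteria: MatchCriteria = MatchCriteria(),
) -> FrocCurve:
    """Breast-based FROC: a breast with lesions counts as detected when any
    of its lesions on any view is matched.  FP rate stays per volume."""
    missing = [k for k in ground_truths if k not in predictions]
    if missing:
        raise ValueError(f"annotated volumes without prediction entries: {missing}")
    n_volumes = len(predictions)
    breasts = {_breast_key(k) for k, v in ground_truths.items() if v}
    if n_volumes == 0 or not breasts:
        raise ValueError("need at least one volume and one breast with lesions")
    points = []
    for _, matched, fp in _sweep(predictions, ground_truths, n_slices, criteria):
        detected = {_breast_key(k) for k, m in matched.items() if m}
        points.append((fp / n_volumes, len(detected & breasts) / len(breasts)))
    if not points:
        points = [(0.0, 0.0)]
    return _finalize(points, unit="breast")


def froc_slice(
    predictions: list[list[PredictedBox]],
    ground_truths: list[list[GroundTruthBox3D]],
    criteria: MatchCriteria = MatchCriteria(),
) -> FrocCurve:
    """2-D FROC over independent crops/slices (no z condition); used for
    validation-time model selection at 2 FP per slice."""
    if len(predictions) != len(ground_truths):
        raise ValueError("predictions and ground truths must align")
    keys = list(range(len(predictions)))
    preds = {(str(k), "", "LCC"): predictions[k] for k in keys}
    # a 1-slice volume makes the z window always contain z=0
    gts = {}
    ns = {}
    for k in keys:
        key = (str(k), "", "LCC")
        gts[key] = ground_truths[k]
        ns[key] = 1
    curve = froc_volume(preds, gts, ns, criteria)
    curve.unit = "slice"
    return curve


def sensitivity_at(curve: FrocCurve, fp_rate: float) -> float:
    """Step-function read-off: sensitivity of the rightmost point with
    fp_per_unit <= fp_rate; 0 if the curve starts beyond fp_rate."""
    if not curve.points:
        raise ValueError("empty FROC curve")
    if fp_rate < 0:
        raise ValueError("fp_rate must be >= 0")
    best = 0.0
    for fp, s in curve.points:
        if fp <= fp_rate:
            best = s
        else:
            break
    return best


def bootstrap_ci(
    predictions: dict,
    ground_truths: dict,
    n_slices: dict,
    metric,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric(preds, gts, n_slices)``, resampling
    patients with replacement.  Resamples with no ground truth are redrawn."""
    patients = sorted({k[0] for k in predictions})
    if not patients:
        raise ValueError("no resampling units")
    by_patient: dict[str, list] = {p: [] for p in patients}
    for key in predictions:
        by_patient[key[0]].append(key)
    rng = np.random.default_rng(seed)
    values = []
    redraws = 0
    for _ in range(n_boot):
        while True:
            chosen = rng.choice(len(patients), size=len(patients), replace=True)
            preds, gts, ns = {}, {}, {}
            for replica, idx in enumerate(chosen):
                for key in by_patient[patients[idx]]:
                    new_key = (f"{key[0]}#{replica}",) + tuple(key[1:])
                    preds[new_key] = predictions[key]
                    gts[new_key] = ground_truths.get(key, [])
                    ns[new_key] = n_slices[key]
            if sum(len(v) for v in gts.values()) > 0:
                break
            redraws += 1
            if redraws > 100 * n_boot:
                raise ValueError("could not draw a resample with ground truth")
        values.append(metric(preds, gts, ns))
    lo = (1.0 - level) / 2.0 * 100.0
    return (float(np.percentile(values, lo)), float(np.percentile(values, 100.0 - lo)))
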