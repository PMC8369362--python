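"""Desk-scale end-to-end benchmark: train a small detector on phantom
lesions and measure breast-based FROC sensitivity on a held-out phantom set.

Shared by the acceptance suite.  One call = one seed; ~2.5 min on one CPU.
"""

from __future__ import annotations

import numpy as np

from dbtdet.detector_core import DetectorConfig, build_detector
from dbtdet.froc_eval import MatchCriteria, froc_breast, sensitivity_at
from dbtdet.ground_truth import ground_truth_box
from dbtdet.inference_post import predict_volume
from dbtdet.io_formats import LesionClass, View
from dbtdet.losses import LossConfig, LossKind
from dbtdet.phantom_sim import PhantomSpec, SMALL_PRESET, generate_volume, random_lesion
from dbtdet.preprocess import preprocess_volume
from dbtdet.train_loop import TrainConfig, TrainingExample, train

N_TRAIN_BENIGN = 3
N_TRAIN_CANCER = 3
N_HELDOUT_NORMAL = 3
N_HELDOUT_BENIGN = 3
N_HELDOUT_CANCER = 3


def _lesion_study(rng, base, patient, study, cls):
    """The two annotated views (CC + MLO of one breast), one lesion each."""
    side = rng.choice(["L", "R"])
    views = [View.LCC, View.LMLO] if side == "L" else [View.RCC, View.RMLO]
    out = []
    for view in views:
        lesion = random_lesion(base, rng, cls)
        spec = PhantomSpec(**SMALL_PRESET, lesions=(lesion,),
                           seed=int(rng.integers(2 ** 31)))
        vol, anns = generate_volume(spec, view=view, patient_id=patient,
                                    study_id=study)
        out.append((vol, anns))
    return out, views


def _clean_volume(rng, patient, study, view):
    spec = PhantomSpec(**SMALL_PRESET, seed=int(rng.integers(2 ** 31)))
    vol, _ = generate_volume(spec, view=view, patient_id=patient, study_id=study)
    return vol


def run_end_to_end(seed: int, max_epochs: int = 30) -> dict:
    """Returns the held-out breast FROC sensitivity at 2 FP/volume plus
    training history, using the paper-default matching criteria."""
    rng = np.random.default_rng(seed)
    base = PhantomSpec(**SMALL_PRESET)

    train_ex, val_ex = [], []
    for i in range(N_TRAIN_BENIGN + N_TRAIN_CANCER):
        cls = LesionClass.BENIGN if i < N_TRAIN_BENIGN else LesionClass.CANCER
        studies, _ = _lesion_study(rng, base, f"T{i}", f"1.{i}", cls)
        for vol, anns in studies:
            pvol, _ = preprocess_volume(vol)
            train_ex.append(TrainingExample(
                volume=pvol,
                boxes=[ground_truth_box(a, pvol.n_slices, "train") for a in anns]))
            val_ex.append(TrainingExample(
                volume=pvol,
                boxes=[ground_truth_box(a, pvol.n_slices, "validation") for a in anns]))

    config = TrainConfig(crop=(192, 192), batch_size=2, max_epochs=max_epochs,
                         patience=max_epochs - 1, seed=seed,
                         loss=LossConfig(kind=LossKind.FOCAL))
    detector = build_detector(DetectorConfig(growth_rate=4, blocks=(1, 1), seed=seed))
    detector, history = train(detector, train_ex, val_ex, config)

    predictions, gts, n_slices = {}, {}, {}

    def add_volume(vol, anns):
        pvol, masks = preprocess_volume(vol)
        key = (vol.patient_id, vol.study_id, vol.view)
        predictions[key] = predict_volume(detector, pvol, masks, threshold=0.05).boxes
        gts[key] = [ground_truth_box(a, pvol.n_slices, "evaluation") for a in anns]
        n_slices[key] = pvol.n_slices

    for i in range(N_HELDOUT_NORMAL):
        for view in View:
            add_volume(_clean_volume(rng, f"HN{i}", f"2.{i}", view), [])
    for i in range(N_HELDOUT_BENIGN + N_HELDOUT_CANCER):
        cls = LesionClass.BENIGN if i < N_HELDOUT_BENIGN else LesionClass.CANCER
        studies, views = _lesion_study(rng, base, f"H{i}", f"3.{i}", cls)
        for vol, anns in studies:
            add_volume(vol, anns)
        for view in (v for v in View if v not in views):
            add_volume(_clean_volume(rng, f"H{i}", f"3.{i}", view), [])

    curve = froc_breast(predictions, gts, n_slices, MatchCriteria())
    return {
        "sensitivity": sensitivity_at(curve, 2.0),
        "curve": curve,
        "history": history,
        "n_volumes": len(predictions),
        "n_breasts": len({(k[0], k[1], k[2].value[0]) for k, v in gts.items() if v}),
    }
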