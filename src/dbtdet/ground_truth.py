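"""Ground-truth construction: 3-D slice spans from 2-D center-slice boxes,
and target-grid encoding for training crops.

The number of slices a lesion is taken to occupy during training is
``round(sqrt((width + height) / 2))`` of the radiologist's full-resolution
box (round half to even, clamped to >= 1).  Validation halves that span;
evaluation instead uses a fixed 25%-of-volume window around the center
slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import LesionAnnotation, LesionClass, LesionType

__all__ = [
    "CELL", "ANCHOR",
    "GroundTruthBox3D", "TargetGrid",
    "positive_slice_count", "training_slice_range", "validation_slice_range",
    "evaluation_slice_range", "encode_target_grid", "decode_target_grid",
    "ground_truth_box",
]

CELL = 96       # grid cell size in preprocessed pixels
ANCHOR = 256.0  # square anchor box side in preprocessed pixels


@dataclass(frozen=True)
class GroundTruthBox3D:
    """2-D box in preprocessed pixels plus an inclusive slice range."""

    x: float
    y: float
    width: float
    height: float
    center_slice: int
    slice_lo: int
    slice_hi: int
    lesion_class: LesionClass
    lesion_type: LesionType
    patient_id: str = ""
    study_id: str = ""
    view: object = None

    def __post_init__(self) -> None:
        if not (self.slice_lo <= self.center_slice <= self.slice_hi):
            raise ValueError("slice range must contain the center slice")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)


@dataclass
class TargetGrid:
    """Binary objectness grid plus regression targets at positive cells.

    ``objectness``: (rows/96, cols/96) in {0, 1}.
    ``regression``: (4, rows/96, cols/96) = (off_x, off_y, log w/256, log h/256),
    defined only where objectness == 1.
    """

    objectness: np.ndarray
    regression: np.ndarray


def positive_slice_count(width: float, height: float) -> int:
    """round(sqrt(mean(width, height))), half to even, clamped to >= 1."""
    if width <= 0 or height <= 0:
        raise ValueError(f"box dims must be positive, got {width}x{height}")
    return max(1, round(math.sqrt((width + height) / 2.0)))


def _span(center_slice: int, count: int, n_slices: int) -> tuple[int, int]:
    if not (0 <= center_slice < n_slices):
        raise ValueError(f"center_slice {center_slice} outside volume of {n_slices} slices")
    # even count: the extra slice goes below the center
    lo = center_slice - count // 2
    hi = lo + count - 1
    return max(0, lo), min(n_slices - 1, hi)


def training_slice_range(center_slice: int, count: int, n_slices: int) -> tuple[int, int]:
    """Span of ``count`` slices centered on ``center_slice``, clipped to the volume."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return _span(center_slice, count, n_slices)


def validation_slice_range(center_slice: int, count: int, n_slices: int) -> tuple[int, int]:
    """Training span with the slice count halved (round half to even, min 1)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return _span(center_slice, max(1, round(count / 2.0)), n_slices)


def evaluation_slice_range(center_slice: int, n_slices: int) -> tuple[int, int]:
    """center +- round(0.25 * n_slices), clipped to the volume."""
    if not (0 <= center_slice < n_slices):
        raise ValueError(f"center_slice {center_slice} outside volume of {n_slices} slices")
    r = round(0.25 * n_slices)
    return max(0, center_slice - r), min(n_slices - 1, center_slice + r)


def ground_truth_box(
    annotation: LesionAnnotation,
    n_slices: int,
    phase: str = "train",
) -> GroundTruthBox3D:
    """Build the 3-D ground-truth box (preprocessed coordinates) for one
    annotation.  ``phase`` is one of train/validation/evaluation and selects
    the slice-span rule; the sqrt rule always uses the full-resolution box."""
    count = positive_slice_count(annotation.width, annotation.height)
    if phase == "train":
        lo, hi = training_slice_range(annotation.center_slice, count, n_slices)
    elif phase == "validation":
        lo, hi = validation_slice_range(annotation.center_slice, count, n_slices)
    elif phase == "evaluation":
        lo, hi = evaluation_slice_range(annotation.center_slice, n_slices)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    half = annotation.halved()
    return GroundTruthBox3D(
        x=half.x, y=half.y, width=half.width, height=half.height,
        center_slice=annotation.center_slice, slice_lo=lo, slice_hi=hi,
        lesion_class=annotation.lesion_class, lesion_type=annotation.lesion_type,
        patient_id=annotation.patient_id, study_id=annotation.study_id,
        view=annotation.view,
    )


def encode_target_grid(
    boxes: list[tuple[float, float, float, float]],
    crop_shape: tuple[int, int],
) -> TargetGrid:
    """Encode (x, y, w, h) boxes in crop coordinates into a target grid.

    The cell containing each box center is positive; offsets are expressed in
    cell widths relative to the cell center, scales as log(dim / anchor).
    One box per cell: on collision the larger-area box wins.
    """
    rows, cols = crop_shape
    if rows % CELL or cols % CELL:
        raise ValueError(f"crop shape {crop_shape} must be a multiple of {CELL}")
    gr, gc = rows // CELL, cols // CELL
    objectness = np.zeros((gr, gc), dtype=np.float32)
    regression = np.zeros((4, gr, gc), dtype=np.float32)
    area = np.zeros((gr, gc), dtype=np.float64)
    for (x, y, w, h) in boxes:
        if w <= 0 or h <= 0:
            raise ValueError("box dims must be positive")
        cx, cy = x + w / 2.0, y + h / 2.0
        i, j = int(cy // CELL), int(cx // CELL)
        if not (0 <= i < gr and 0 <= j < gc):
            continue  # center outside the crop: no target
        if objectness[i, j] and area[i, j] >= w * h:
            continue
        cell_cx, cell_cy = (j + 0.5) * CELL, (i + 0.5) * CELL
        objectness[i, j] = 1.0
        area[i, j] = w * h
        regression[:, i, j] = (
            (cx - cell_cx) / CELL, (cy - cell_cy) / CELL,
            math.log(w / ANCHOR), math.log(h / ANCHOR),
        )
    return TargetGrid(objectness=objectness, regression=regression)


def decode_target_grid(grid: TargetGrid) -> list[tuple[float, float, float, float]]:
    """Inverse of :func:`encode_target_grid` (row-major cell order)."""
    out = []
    gr, gc = grid.objectness.shape
    for i in range(gr):
        for j in range(gc):
            if grid.objectness[i, j] <= 0:
                continue
            off_x, off_y, sw, sh = (float(v) for v in grid.regression[:, i, j])
            cx = (j + 0.5) * CELL + off_x * CELL
            cy = (i + 0.5) * CELL + off_y * CELL
            w, h = ANCHOR * math.exp(sw), ANCHOR * math.exp(sh)
            out.append((cx - w / 2.0, cy - h / 2.0, w, h))
    return out
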