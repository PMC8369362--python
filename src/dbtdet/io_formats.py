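"""Domain types and stable file formats: DICOM volumes and CSV tables.

Coordinate conventions used throughout the package:

* 0-based indices; ``x`` indexes columns, ``y`` indexes rows.
* Boxes are half-open: ``[x, x + width) x [y, y + height)``.
* Annotation coordinates are stored at full (raw) resolution and divided by
  2 (floor) when mapped onto preprocessed images.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._dicom import DicomFormatError, read_dicom, write_dicom

__all__ = [
    "View",
    "LesionClass",
    "LesionType",
    "Volume",
    "LesionAnnotation",
    "PredictedBox",
    "VolumeIndexEntry",
    "SchemaError",
    "ValidationError",
    "read_volume",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "read_volume_index",
    "write_volume_index",
]

ANNOTATION_COLUMNS = [
    "PatientID", "StudyUID", "View", "X", "Y", "Width", "Height",
    "Slice", "Class", "LesionType",
]
PREDICTION_COLUMNS = [
    "PatientID", "StudyUID", "View", "X", "Y", "Width", "Height", "Z", "Score",
]
INDEX_COLUMNS = ["PatientID", "StudyUID", "View", "Path", "NumSlices", "Group"]

GROUPS = ("normal", "actionable", "benign", "cancer")


class View(str, enum.Enum):
    LCC = "LCC"
    RCC = "RCC"
    LMLO = "LMLO"
    RMLO = "RMLO"

    @property
    def laterality(self) -> str:
        return self.value[0]


class LesionClass(str, enum.Enum):
    CANCER = "cancer"
    BENIGN = "benign"


class LesionType(str, enum.Enum):
    MASS = "mass"
    ARCHITECTURAL_DISTORTION = "architectural_distortion"


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong header."""


class ValidationError(ValueError):
    """A record violates a field-level invariant."""


@dataclass
class Volume:
    """A DBT reconstruction volume: (slice, row, col) nonnegative intensities."""

    pixels: np.ndarray
    view: View
    patient_id: str
    study_id: str
    window_center: float
    window_width: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValidationError("Volume pixels must be 3-D (slice, row, col)")
        if self.pixels.shape[0] < 1:
            raise ValidationError("Volume must have at least one slice")
        self.view = View(self.view)

    @property
    def n_slices(self) -> int:
        return int(self.pixels.shape[0])


@dataclass(frozen=True)
class LesionAnnotation:
    """Radiologist 2-D box on a center slice, at full resolution."""

    patient_id: str
    study_id: str
    view: View
    x: int
    y: int
    width: int
    height: int
    center_slice: int
    lesion_class: LesionClass
    lesion_type: LesionType

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"annotation box must have positive dims, got {self.width}x{self.height}"
            )
        if self.center_slice < 0:
            raise ValidationError("center_slice must be >= 0")

    def halved(self) -> "LesionAnnotation":
        """Map the box onto the 2x-downscaled image (floor division)."""
        return replace(
            self, x=self.x // 2, y=self.y // 2,
            width=max(1, self.width // 2), height=max(1, self.height // 2),
        )


@dataclass(frozen=True)
class PredictedBox:
    """A decoded, scored 2-D box with a volume slice index."""

    x: float
    y: float
    width: float
    height: float
    z: int
    score: float
    patient_id: str = ""
    study_id: str = ""
    view: View | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("predicted box must have positive dims")
        if not (0.0 < self.score <= 1.0):
            raise ValidationError(f"score must be in (0, 1], got {self.score}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


@dataclass(frozen=True)
class VolumeIndexEntry:
    patient_id: str
    study_id: str
    view: View
    path: str
    n_slices: int
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")


# ---------------------------------------------------------------------------
# DICOM volumes


def read_volume(path: str | Path) -> Volume:
    """Read a DBT volume from a multi-frame DICOM file or a slice directory.

    Slices are ordered by InstanceNumber (series) or frame order (multi-frame),
    regardless of filesystem listing order.  Missing window tags fall back to
    center=(min+max)/2 and width=max-min of the pixel data.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise DicomFormatError(f"empty DICOM directory: {path}")
        records = [read_dicom(p) for p in files]
        series = {r.get("SeriesInstanceUID") for r in records}
        if len(series) > 1:
            raise DicomFormatError(
                f"directory {path} mixes {len(series)} series: {sorted(map(str, series))}"
            )
        records.sort(key=lambda r: int(r.get("InstanceNumber", 0)))
        pixels = np.stack([_frame(r) for r in records])
        meta = records[0]
    else:
        meta = read_dicom(path)
        pixels = np.asarray(meta["pixels"])
        if pixels.ndim == 2:
            pixels = pixels[None]

    center = meta.get("WindowCenter")
    width = meta.get("WindowWidth")
    if center is None or width is None or float(width) <= 0:
        lo, hi = float(pixels.min()), float(pixels.max())
        center = (lo + hi) / 2.0
        width = max(hi - lo, 1.0)
    return Volume(
        pixels=pixels,
        view=View(str(meta.get("SeriesDescription", "LCC"))),
        patient_id=str(meta.get("PatientID", "")),
        study_id=str(meta.get("StudyInstanceUID", "")),
        window_center=float(center),
        window_width=float(width),
    )


def _frame(record: dict) -> np.ndarray:
    pixels = np.asarray(record["pixels"])
    if pixels.ndim == 3:
        if pixels.shape[0] != 1:
            raise DicomFormatError("multi-frame file found inside a slice directory")
        pixels = pixels[0]
    return pixels


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as a single multi-frame DICOM file."""
    write_dicom(
        path,
        {
            "PatientID": volume.patient_id,
            "StudyInstanceUID": volume.study_id,
            "SeriesInstanceUID": f"{volume.study_id}.{volume.view.value}",
            "SeriesDescription": volume.view.value,
            "InstanceNumber": 1,
            "WindowCenter": f"{volume.window_center:g}",
            "WindowWidth": f"{volume.window_width:g}",
        },
        np.asarray(volume.pixels, dtype=np.uint16),
    )


# ---------------------------------------------------------------------------
# CSV tables


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected {expected}")


def _parse_enum(cls, raw: str, row: int, path):
    try:
        return cls(str(raw).strip().lower().replace(" ", "_"))
    except ValueError:
        valid = [m.value for m in cls]
        raise ValidationError(f"{path} row {row}: {raw!r} not one of {valid}") from None


def read_annotations(path: str | Path) -> list[LesionAnnotation]:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, ANNOTATION_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ann = LesionAnnotation(
                patient_id=str(row.PatientID),
                study_id=str(row.StudyUID),
                view=View(str(row.View).strip().upper()),
                x=int(row.X), y=int(row.Y),
                width=int(row.Width), height=int(row.Height),
                center_slice=int(row.Slice),
                lesion_class=_parse_enum(LesionClass, row.Class, i, path),
                lesion_type=_parse_enum(LesionType, row.LesionType, i, path),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
        out.append(ann)
    return out


def write_annotations(annotations: list[LesionAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "PatientID": a.patient_id, "StudyUID": a.study_id,
                "View": a.view.value, "X": a.x, "Y": a.y,
                "Width": a.width, "Height": a.height, "Slice": a.center_slice,
                "Class": a.lesion_class.value, "LesionType": a.lesion_type.value,
            }
            for a in annotations
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictedBox]:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, PREDICTION_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                PredictedBox(
                    x=float(row.X), y=float(row.Y),
                    width=float(row.Width), height=float(row.Height),
                    z=int(row.Z), score=float(row.Score),
                    patient_id=str(row.PatientID), study_id=str(row.StudyUID),
                    view=View(str(row.View).strip().upper()),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    return out


def write_predictions(boxes: list[PredictedBox], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "PatientID": b.patient_id, "StudyUID": b.study_id,
                "View": b.view.value if b.view is not None else "",
                "X": repr(float(b.x)), "Y": repr(float(b.y)),
                "Width": repr(float(b.width)), "Height": repr(float(b.height)),
                "Z": b.z, "Score": repr(float(b.score)),
            }
            for b in boxes
        ],
        columns=PREDICTION_COLUMNS,
    ).to_csv(path, index=False)


def read_volume_index(path: str | Path) -> list[VolumeIndexEntry]:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, INDEX_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                VolumeIndexEntry(
                    patient_id=str(row.PatientID), study_id=str(row.StudyUID),
                    view=View(str(row.View).strip().upper()), path=str(row.Path),
                    n_slices=int(row.NumSlices), group=str(row.Group).strip().lower(),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    return out


def write_volume_index(entries: list[VolumeIndexEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "PatientID": e.patient_id, "StudyUID": e.study_id,
                "View": e.view.value, "Path": e.path,
                "NumSlices": e.n_slices, "Group": e.group,
            }
            for e in entries
        ],
        columns=INDEX_COLUMNS,
    ).to_csv(path, index=False)
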