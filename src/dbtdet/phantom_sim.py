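"""Seed-deterministic synthetic DBT-like phantom volumes.

Phantoms are statistical look-alikes of reconstructed DBT views, not physics
simulations: a half-elliptical breast of textured tissue against a zero
background, a thin bright skin rim, and sparse bright lesions (Gaussian-blob
masses or spiculated architectural distortions).  Lesions are annotated the
way the real dataset is annotated: a tight 2-D box on the lesion's center
slice, at full (raw) resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    LesionAnnotation, LesionClass, LesionType, View, Volume, VolumeIndexEntry,
    write_annotations, write_volume, write_volume_index,
)

__all__ = ["LesionSpec", "PhantomSpec", "generate_volume", "generate_dataset",
           "random_lesion", "TINY_PRESET", "SMALL_PRESET", "REALISTIC_PRESET"]

# raw-resolution presets: (n_slices, rows, cols)
TINY_PRESET = dict(n_slices=12, rows=384, cols=256)
SMALL_PRESET = dict(n_slices=40, rows=768, cols=512)
REALISTIC_PRESET = dict(n_slices=64, rows=2048, cols=1024)

WINDOW_CENTER = 500.0
WINDOW_WIDTH = 1000.0
TISSUE_LEVEL = 300.0
SKIN_LEVEL = 900.0


@dataclass(frozen=True)
class LesionSpec:
    kind: LesionType
    center: tuple[int, int, int]        # (x, y, z) raw pixels / slice
    size: int                           # characteristic diameter, raw px
    contrast: float
    lesion_class: LesionClass

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("lesion size must be >= 8 px")
        if self.contrast <= 0:
            raise ValueError("lesion contrast must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    n_slices: int = SMALL_PRESET["n_slices"]
    rows: int = SMALL_PRESET["rows"]
    cols: int = SMALL_PRESET["cols"]
    breast_axes: tuple[float, float] | None = None  # (semi-axis rows, semi-axis cols)
    skin_thickness: int = 6
    noise: tuple[float, float] = (TISSUE_LEVEL, 40.0)
    lesions: tuple[LesionSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 4:
            raise ValueError("phantoms need at least 4 slices")


from functools import lru_cache


@lru_cache(maxsize=64)
def _level_mask(rows: int, cols: int, axes: tuple[float, float] | None,
                margin: int) -> np.ndarray:
    """Breast half-ellipse shrunk inward by ``margin`` px (margin 0 = region).

    The shrink is taken as a level set of the ellipse field, which matches
    erosion for this convex shape but is much cheaper at full resolution.
    Cached: the geometry is shared by every volume of a dataset.
    """
    a, b = axes or (rows * 0.45, cols * 0.85)
    y, x = np.mgrid[0:rows, 0:cols]
    cy = rows / 2.0
    field = np.sqrt(((y - cy) / a) ** 2 + (x / b) ** 2)
    mask = field <= 1.0 - margin / min(a, b)
    mask.flags.writeable = False
    return mask


def _breast_region(spec: PhantomSpec) -> np.ndarray:
    """Half-ellipse flush with the chest wall (image left edge)."""
    return _level_mask(spec.rows, spec.cols, spec.breast_axes, 0)


def _interior(spec: PhantomSpec, margin: int) -> np.ndarray:
    return _level_mask(spec.rows, spec.cols, spec.breast_axes, margin)


def _add_mass(vol: np.ndarray, lesion: LesionSpec) -> None:
    cx, cy, cz = lesion.center
    sigma = lesion.size / 4.0
    sigma_z = max(0.5, lesion.size / 8.0 / 2.0)  # slices are ~2x coarser than px
    r = int(math.ceil(3 * sigma))
    n, rows, cols = vol.shape
    y0, y1 = max(0, cy - r), min(rows, cy + r + 1)
    x0, x1 = max(0, cx - r), min(cols, cx + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2)))
    for z in range(max(0, int(cz - 3 * sigma_z)), min(n, int(cz + 3 * sigma_z) + 1)):
        amp = lesion.contrast * math.exp(-((z - cz) ** 2) / (2 * sigma_z ** 2))
        vol[z, y0:y1, x0:x1] += amp * blob


def _add_distortion(vol: np.ndarray, lesion: LesionSpec, rng: np.random.Generator) -> None:
    cx, cy, cz = lesion.center
    n, rows, cols = vol.shape
    n_rays = int(rng.integers(8, 17))
    length = lesion.size / 2.0
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n_rays)
    widths = rng.integers(1, 3, size=n_rays)
    z_sigma = max(0.5, lesion.size / 16.0 / 2.0)
    stamp = np.zeros((rows, cols), dtype=np.float32)
    for theta, width in zip(angles, widths):
        steps = int(length * 2)
        for s in range(steps):
            t = s / 2.0
            px = cx + t * math.cos(theta)
            py = cy + t * math.sin(theta)
            fade = 1.0 - 0.5 * (t / length)
            for dy in range(-int(width // 2), int((width + 1) // 2) + 1):
                for dx in range(-int(width // 2), int((width + 1) // 2) + 1):
                    ix, iy = int(round(px)) + dx, int(round(py)) + dy
                    if 0 <= iy < rows and 0 <= ix < cols:
                        stamp[iy, ix] = max(stamp[iy, ix], fade)
    # faint core
    r = int(lesion.size / 4)
    y0, y1 = max(0, cy - r), min(rows, cy + r + 1)
    x0, x1 = max(0, cx - r), min(cols, cx + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    core = 0.5 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (lesion.size / 8.0) ** 2)))
    stamp[y0:y1, x0:x1] = np.maximum(stamp[y0:y1, x0:x1], core)
    for z in range(max(0, int(cz - 3 * z_sigma)), min(n, int(cz + 3 * z_sigma) + 1)):
        amp = lesion.contrast * math.exp(-((z - cz) ** 2) / (2 * z_sigma ** 2))
        vol[z] += amp * stamp


def generate_volume(
    spec: PhantomSpec,
    view: View = View.LCC,
    patient_id: str = "P0000",
    study_id: str = "1.2.0.0",
) -> tuple[Volume, list[LesionAnnotation]]:
    """Render one phantom volume and its annotations; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    region = _breast_region(spec)
    interior = _interior(spec, spec.skin_thickness)
    safe = _interior(spec, spec.skin_thickness + 16)

    mean, sd = spec.noise
    vol = np.zeros((spec.n_slices, spec.rows, spec.cols), dtype=np.float32)
    for z in range(spec.n_slices):
        tissue = rng.normal(mean, sd, size=(spec.rows, spec.cols)).astype(np.float32)
        slice_ = np.where(interior, tissue, 0.0)
        slice_[region & ~interior] = SKIN_LEVEL
        vol[z] = slice_

    annotations = []
    for lesion in spec.lesions:
        cx, cy, cz = lesion.center
        if not (0 <= cz < spec.n_slices) or not (0 <= cy < spec.rows and 0 <= cx < spec.cols) \
                or not safe[cy, cx]:
            raise ValueError(f"lesion center {lesion.center} outside the breast interior")
        if lesion.kind is LesionType.MASS:
            _add_mass(vol, lesion)
        else:
            _add_distortion(vol, lesion, rng)
        half = lesion.size // 2
        annotations.append(
            LesionAnnotation(
                patient_id=patient_id, study_id=study_id, view=view,
                x=cx - half, y=cy - half, width=2 * half, height=2 * half,
                center_slice=cz, lesion_class=lesion.lesion_class,
                lesion_type=lesion.kind,
            )
        )

    vol = np.where(region, np.clip(vol, 1.0, WINDOW_WIDTH - 1.0), 0.0)
    volume = Volume(
        pixels=vol.astype(np.uint16), view=view, patient_id=patient_id,
        study_id=study_id, window_center=WINDOW_CENTER, window_width=WINDOW_WIDTH,
    )
    return volume, annotations


def random_lesion(
    spec: PhantomSpec,
    rng: np.random.Generator,
    lesion_class: LesionClass,
    kind: LesionType | None = None,
    contrast: float = 400.0,
) -> LesionSpec:
    """Place a lesion uniformly inside the safe breast interior."""
    size = int(rng.integers(48, 81))
    safe = np.array(_interior(spec, spec.skin_thickness + 48))
    # the chest-wall (left) image edge is not eroded by the breast margin;
    # additionally require the whole annotation box to fit inside the image
    half = size // 2
    pad = half + 8
    safe[:pad, :] = False
    safe[-pad:, :] = False
    safe[:, :pad] = False
    safe[:, -pad:] = False
    ys, xs = np.nonzero(safe)
    if len(ys) == 0:
        raise ValueError("breast interior too small for lesion placement")
    i = int(rng.integers(len(ys)))
    z = int(rng.integers(spec.n_slices // 4, 3 * spec.n_slices // 4 + 1))
    if kind is None:
        kind = LesionType.MASS if rng.random() < 0.75 else LesionType.ARCHITECTURAL_DISTORTION
    return LesionSpec(kind=kind, center=(int(xs[i]), int(ys[i]), z), size=size,
                      contrast=contrast, lesion_class=lesion_class)


def _study_views(
    base_spec: PhantomSpec,
    rng: np.random.Generator,
    patient_id: str,
    study_id: str,
    group: str,
) -> tuple[list[tuple[Volume, View]], list[LesionAnnotation]]:
    """Render the four views of one study; lesions go on one breast's two views."""
    from dataclasses import replace as _replace

    volumes = []
    annotations = []
    lesion_side = rng.choice(["L", "R"]) if group in ("benign", "cancer", "actionable") else None
    for view in (View.LCC, View.RCC, View.LMLO, View.RMLO):
        lesions: tuple[LesionSpec, ...] = ()
        if lesion_side is not None and view.laterality == lesion_side:
            if group == "actionable":
                # subtle sub-contrast finding, never annotated
                lesion = random_lesion(base_spec, rng, LesionClass.BENIGN,
                                       contrast=1.5 * base_spec.noise[1])
            else:
                cls = LesionClass.CANCER if group == "cancer" else LesionClass.BENIGN
                lesion = random_lesion(base_spec, rng, cls)
            lesions = (lesion,)
        spec = _replace(base_spec, lesions=lesions, seed=int(rng.integers(2 ** 31)))
        volume, anns = generate_volume(spec, view=view, patient_id=patient_id,
                                       study_id=study_id)
        volumes.append((volume, view))
        if group in ("benign", "cancer"):
            annotations.extend(anns)
    return volumes, annotations


def generate_dataset(
    n_normal: int,
    n_actionable: int,
    n_benign: int,
    n_cancer: int,
    out_dir: str | Path,
    seed: int = 0,
    preset: dict | None = None,
) -> tuple[Path, Path]:
    """Write a phantom dataset: multi-frame DICOM volumes (4 views per study),
    volume-index.csv, and annotations.csv for biopsied (benign/cancer) lesions.

    Returns (index_path, annotations_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    preset = dict(SMALL_PRESET if preset is None else preset)
    base_spec = PhantomSpec(**preset)
    rng = np.random.default_rng(seed)

    entries = []
    annotations = []
    counter = 0
    for group, count in (("normal", n_normal), ("actionable", n_actionable),
                         ("benign", n_benign), ("cancer", n_cancer)):
        for _ in range(count):
            counter += 1
            patient_id = f"P{counter:04d}"
            study_id = f"1.2.826.0.{seed}.{counter}"
            volumes, anns = _study_views(base_spec, rng, patient_id, study_id, group)
            annotations.extend(anns)
            for volume, view in volumes:
                rel = f"{patient_id}_{view.value}.dcm"
                write_volume(volume, out_dir / rel)
                entries.append(VolumeIndexEntry(
                    patient_id=patient_id, study_id=study_id, view=view,
                    path=rel, n_slices=volume.n_slices, group=group,
                ))

    index_path = out_dir / "volume-index.csv"
    ann_path = out_dir / "annotations.csv"
    write_volume_index(entries, index_path)
    write_annotations(annotations, ann_path)
    return index_path, ann_path
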