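"""Volume preprocessing: window leveling, 2x downscale, breast masking.

Steps run in this order per slice: window-level -> downscale -> mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_formats import Volume

__all__ = ["BreastMask", "window_level", "downscale_2x", "breast_mask", "preprocess_volume"]

DEFAULT_EROSION_RADIUS = 5


@dataclass
class BreastMask:
    """Boolean breast-region mask aligned with one preprocessed slice."""

    mask: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def window_level(slice_: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linearly map [center - width/2, center + width/2] onto [0, 1], clipping outside."""
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = center - width / 2.0
    return np.clip((np.asarray(slice_, dtype=np.float32) - lo) / width, 0.0, 1.0)


def downscale_2x(slice_: np.ndarray) -> np.ndarray:
    """2x2 local-mean downscale; a trailing odd row/column is dropped."""
    a = np.asarray(slice_, dtype=np.float32)
    h, w = a.shape[0] // 2 * 2, a.shape[1] // 2 * 2
    a = a[:h, :w]
    return a.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def disk_element(radius: int) -> np.ndarray:
    """Discrete disk {(di, dj): di^2 + dj^2 <= radius^2}."""
    r = int(radius)
    di, dj = np.mgrid[-r:r + 1, -r:r + 1]
    return (di * di + dj * dj) <= r * r


def breast_mask(slice_: np.ndarray, radius: int = DEFAULT_EROSION_RADIUS) -> BreastMask:
    """Erode nonzero pixels with a disk of ``radius`` px, keep the largest
    8-connected component.  May be empty."""
    nonzero = np.asarray(slice_) > 0
    eroded = ndimage.binary_erosion(nonzero, structure=disk_element(radius))
    if not eroded.any():
        return BreastMask(np.zeros_like(nonzero))
    labels, n = ndimage.label(eroded, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return BreastMask(eroded)
    counts = np.bincount(labels.ravel())[1:]
    return BreastMask(labels == (int(np.argmax(counts)) + 1))


def preprocess_volume(volume: Volume, radius: int = DEFAULT_EROSION_RADIUS) -> tuple[Volume, list[BreastMask]]:
    """Window-level and downscale every slice, then compute per-slice masks."""
    slices = []
    masks = []
    for k in range(volume.n_slices):
        s = window_level(volume.pixels[k], volume.window_center, volume.window_width)
        s = downscale_2x(s)
        slices.append(s)
        masks.append(breast_mask(s, radius=radius))
    return replace(volume, pixels=np.stack(slices)), masks
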