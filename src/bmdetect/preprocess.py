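"""Brain extraction and per-slice intensity normalization.

Detection operates on skull-stripped volumes whose brain voxels are min-max
mapped to [0, 1] slice by slice.  Brain extraction here is a deliberately
simple morphological procedure — automatic (Otsu) thresholding, a
morphological opening, the largest 3D connected component, and hole filling
— which is adequate for phantom volumes whose skull rim is geometrically
separated from the brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .core import Volume3D

__all__ = [
    "BrainMask",
    "ExtractionError",
    "BrainExtractor",
    "SliceNormalizer",
    "extract_brain",
    "normalize_slices",
]


class ExtractionError(RuntimeError):
    """Brain extraction found no usable foreground."""


@dataclass
class BrainMask:
    """Binary brain mask congruent with a :class:`Volume3D` grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("brain mask must be 3D")


class BrainExtractor(BaseEstimator):
    """Threshold-and-morphology brain extractor.

    The procedure is idempotent: extracting from an already-stripped volume
    reproduces the same mask (morphological opening is idempotent, and the
    largest-component / hole-filling steps are fixed points on its output).
    """

    def fit(self, X=None, y=None):  # rule-based; nothing to estimate
        return self

    def extract(self, v: Volume3D) -> tuple[BrainMask, Volume3D]:
        arr = np.asarray(v.data)
        if np.all(arr == arr.flat[0]):
            raise ExtractionError("constant volume: empty foreground")
        fg = arr > threshold_otsu(arr)
        if not fg.any():
            raise ExtractionError("empty foreground after thresholding")
        struct = ndi.generate_binary_structure(3, 1)
        opened = ndi.binary_opening(fg, structure=struct)
        if not opened.any():
            raise ExtractionError("empty foreground after opening")
        labels, n = ndi.label(opened, structure=struct)
        if n == 0:
            raise ExtractionError("no connected foreground component")
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = ndi.binary_fill_holes(labels == int(sizes.argmax()))
        stripped = Volume3D(
            data=np.where(mask, arr, 0).astype(arr.dtype, copy=False),
            pixel_size_mm=v.pixel_size_mm,
            slice_thickness_mm=v.slice_thickness_mm,
            scan_id=v.scan_id,
        )
        return BrainMask(mask=mask), stripped


class SliceNormalizer(BaseEstimator):
    """Per-slice min-max normalization of brain voxels to [0, 1].

    The minimum and maximum are taken over brain voxels only, so the zeroed
    background does not pin the lower end of the map; background stays 0,
    and a slice whose brain intensities are constant maps to 0.
    """

    def fit(self, X=None, y=None):
        return self

    def transform(self, v: Volume3D, m: BrainMask) -> Volume3D:
        arr = np.asarray(v.data, dtype=np.float32)
        mask = m.mask
        if mask.shape != arr.shape:
            raise ValueError("mask shape does not match volume shape")
        out = np.zeros_like(arr, dtype=np.float32)
        for k in range(arr.shape[0]):
            sel = mask[k]
            if not sel.any():
                continue
            vals = arr[k][sel]
            mn = float(vals.min())
            mx = float(vals.max())
            if mx > mn:
                out[k][sel] = (vals - mn) / (mx - mn)
        return Volume3D(
            data=out,
            pixel_size_mm=v.pixel_size_mm,
            slice_thickness_mm=v.slice_thickness_mm,
            scan_id=v.scan_id,
        )


def extract_brain(v: Volume3D) -> tuple[BrainMask, Volume3D]:
    """Extract the brain mask and the skull-stripped volume."""
    return BrainExtractor().extract(v)


def normalize_slices(v: Volume3D, m: BrainMask) -> Volume3D:
    """Min-max map each slice's brain voxels to [0, 1]; background stays 0."""
    return SliceNormalizer().transform(v, m)
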