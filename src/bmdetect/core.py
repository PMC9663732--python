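"""Geometric primitives and I/O shared across the detection framework.

The unit of annotation is an axis-aligned rectangle on one axial slice
(:class:`Box2D`); rectangles on adjacent slices are grouped into a 3D lesion
(:class:`Lesion3D`), the clinical unit of evaluation.  Boxes live on a
half-open real rectangle ``[x, x+w) x [y, y+h)`` in pixel units, with ``x``
indexing columns and ``y`` indexing rows (0-based), so the area is exactly
``w*h`` and intersection-over-union is computed on continuous rectangles.

Volumes are stored slice-major ``(slice, row, col)`` with voxel geometry in
millimetres; NIfTI-1 is the on-disk format, with the array transposed to the
``(col, row, slice)`` axis order NIfTI expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Box2D",
    "Lesion3D",
    "Volume3D",
    "InvalidBoxError",
    "BoxParseError",
    "VolumeDimensionError",
    "iou",
    "read_boxes",
    "write_boxes",
    "read_volume",
    "write_volume",
]

BOX_COLUMNS = ["scan_id", "slice_index", "x", "y", "w", "h", "score", "lesion_id"]
_REQUIRED = ["scan_id", "slice_index", "x", "y", "w", "h"]


class InvalidBoxError(ValueError):
    """A bounding box violates its geometric invariants."""


class BoxParseError(ValueError):
    """A box table on disk could not be parsed."""


class VolumeDimensionError(ValueError):
    """An image on disk is not a 3D volume."""


@dataclass
class Box2D:
    """Axis-aligned rectangle on one axial slice.

    Parameters
    ----------
    slice_index : int
        0-based slice the box lives on.
    x, y : float
        Left column / top row of the rectangle (0-based pixels).
    w, h : float
        Extents in pixels; strictly positive.
    score : float, optional
        Detection confidence in [0, 1]; ``None`` for ground-truth labels.
    lesion_id : int, optional
        1-based lesion number assigned by the linker; ``None`` if unlinked.
    scan_id : str, optional
        Identifier of the scan the box belongs to.
    """

    slice_index: int
    x: float
    y: float
    w: float
    h: float
    score: float | None = None
    lesion_id: int | None = None
    scan_id: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)
                and np.isfinite(self.w) and np.isfinite(self.h)):
            raise InvalidBoxError(f"non-finite box geometry: {self}")
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(f"box extents must be positive, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise InvalidBoxError(f"box origin must be non-negative, got x={self.x}, y={self.y}")
        if self.slice_index < 0:
            raise InvalidBoxError(f"slice_index must be >= 0, got {self.slice_index}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise InvalidBoxError(f"score must lie in [0, 1], got {self.score}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    def with_lesion_id(self, lesion_id: int) -> "Box2D":
        return replace(self, lesion_id=lesion_id)


def iou(a: Box2D, b: Box2D) -> float:
    """Intersection over union of two boxes as continuous rectangles.

    ``slice_index`` is ignored: this is pure 2D geometry, used both for
    adjacent-slice linking (threshold 0.3) and prediction-to-label matching
    (threshold 0.5).
    """
    if a.w <= 0 or a.h <= 0 or b.w <= 0 or b.h <= 0:
        raise InvalidBoxError("iou requires boxes with positive extents")
    iw = min(a.x2, b.x2) - max(a.x, b.x)
    ih = min(a.y2, b.y2) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


@dataclass
class Lesion3D:
    """A numbered group of boxes across adjacent slices — one 3D lesion."""

    lesion_id: int
    boxes: list[Box2D]

    def __post_init__(self) -> None:
        if self.lesion_id < 1:
            raise ValueError(f"lesion_id must be >= 1, got {self.lesion_id}")
        if not self.boxes:
            raise ValueError("a lesion must contain at least one box")

    @property
    def slices(self) -> list[int]:
        return sorted({b.slice_index for b in self.boxes})

    @property
    def slice_span(self) -> int:
        return len(self.slices)

    def boxes_on(self, slice_index: int) -> list[Box2D]:
        return [b for b in self.boxes if b.slice_index == slice_index]


@dataclass
class Volume3D:
    """A 3D intensity volume with voxel geometry metadata.

    ``data`` is indexed ``(slice, row, col)``; ``pixel_size_mm`` is the
    in-plane ``(row, col)`` spacing and ``slice_thickness_mm`` the spacing
    along the slice axis.
    """

    data: np.ndarray
    pixel_size_mm: tuple[float, float]
    slice_thickness_mm: float
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeDimensionError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        pr, pc = self.pixel_size_mm
        if pr <= 0 or pc <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel spacings must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Box tables (CSV with a JSON alternative carrying identical fields)
# ---------------------------------------------------------------------------

def _box_from_record(rec: dict, row_label: object) -> Box2D:
    try:
        score = rec.get("score")
        score = None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score)
        lid = rec.get("lesion_id")
        lid = None if lid is None or (isinstance(lid, float) and np.isnan(lid)) else int(lid)
        return Box2D(
            slice_index=int(rec["slice_index"]),
            x=float(rec["x"]),
            y=float(rec["y"]),
            w=float(rec["w"]),
            h=float(rec["h"]),
            score=score,
            lesion_id=lid,
            scan_id=None if rec.get("scan_id") is None else str(rec["scan_id"]),
        )
    except (InvalidBoxError, TypeError, ValueError) as exc:
        raise BoxParseError(f"row {row_label}: {exc}") from exc


def read_boxes(path: str | Path) -> list[Box2D]:
    """Read a box table from CSV (or JSON, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [_box_from_record(rec, i) for i, rec in enumerate(records)]
    try:
        df = pd.read_csv(path, dtype={"scan_id": str})
    except pd.errors.EmptyDataError as exc:
        raise BoxParseError(f"{path}: empty file without header") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise BoxParseError(f"{path}: missing required column(s) {missing}")
    boxes = []
    for i, rec in enumerate(df.to_dict("records")):
        boxes.append(_box_from_record(rec, i))
    return boxes


def write_boxes(boxes: list[Box2D], path: str | Path) -> None:
    """Write a box table to CSV (or JSON, by extension); lossless round-trip."""
    path = Path(path)
    records = [
        {
            "scan_id": b.scan_id,
            "slice_index": b.slice_index,
            "x": b.x,
            "y": b.y,
            "w": b.w,
            "h": b.h,
            "score": b.score,
            "lesion_id": b.lesion_id,
        }
        for b in boxes
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=1))
        return
    df = pd.DataFrame(records, columns=BOX_COLUMNS)
    if not df.empty:
        df["lesion_id"] = df["lesion_id"].astype("Int64")
    # str() on Python floats is repr-exact, so floats survive the round trip
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Volumes (NIfTI-1)
# ---------------------------------------------------------------------------

def _scan_id_from_path(path: Path) -> str:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return path.stem


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 volume; spacings are taken from the header zooms."""
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise VolumeDimensionError(f"{path}: expected a 3D image, got ndim={arr.ndim}")
    pc, pr, st = (float(z) for z in img.header.get_zooms()[:3])
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return Volume3D(
        data=data,
        pixel_size_mm=(pr, pc),
        slice_thickness_mm=st,
        scan_id=_scan_id_from_path(path),
    )


def write_volume(v: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving geometry metadata."""
    pr, pc = v.pixel_size_mm
    affine = np.diag([pc, pr, v.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(v.data.transpose(2, 1, 0)), affine)
    img.header.set_zooms((pc, pr, v.slice_thickness_mm))
    nib.save(img, str(path))
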