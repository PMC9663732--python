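"""Merge per-slice boxes into numbered 3D lesions.

Clinically the unit of interest is the lesion, not the slice.  Boxes on
slices whose indices differ by exactly 1 are considered the same lesion when
their 2D IoU exceeds a threshold (default 0.3); connected components of this
adjacency graph are the lesions.  Because a lesion with a diameter above the
5 mm floor must appear on two or more 3 mm slices, components confined to a
single slice are discarded (``min_slices=2``) for both labels and
predictions.

Lesion numbers are assigned 1..K in order of each component's minimum
``(slice_index, y, x)`` key, so the partition and the numbering are
invariant to the input ordering of the boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .core import Box2D, Lesion3D, iou

__all__ = ["LinkerConfig", "LesionLinker", "MixedScanError", "link_boxes", "lesion_summary"]


class MixedScanError(ValueError):
    """Boxes from more than one scan were passed to the linker."""


@dataclass
class LinkerConfig:
    adjacency_iou: float = 0.3
    min_slices: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.adjacency_iou <= 1.0):
            raise ValueError("adjacency_iou must lie in [0, 1]")
        if self.min_slices < 1:
            raise ValueError("min_slices must be >= 1")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


class LesionLinker(BaseEstimator):
    """Adjacent-slice IoU linker with a multi-slice filter."""

    def __init__(self, adjacency_iou: float = 0.3, min_slices: int = 2):
        self.adjacency_iou = adjacency_iou
        self.min_slices = min_slices

    def fit(self, X=None, y=None):
        return self

    def transform(self, boxes: list[Box2D]) -> list[Lesion3D]:
        cfg = LinkerConfig(adjacency_iou=self.adjacency_iou, min_slices=self.min_slices)
        if not boxes:
            return []
        scan_ids = {b.scan_id for b in boxes if b.scan_id is not None}
        if len(scan_ids) > 1:
            raise MixedScanError(f"boxes from multiple scans: {sorted(scan_ids)}")

        by_slice: dict[int, list[int]] = {}
        for i, b in enumerate(boxes):
            by_slice.setdefault(b.slice_index, []).append(i)

        uf = _UnionFind(len(boxes))
        for s in sorted(by_slice):
            if s + 1 not in by_slice:
                continue
            for i in by_slice[s]:
                for j in by_slice[s + 1]:
                    if iou(boxes[i], boxes[j]) > cfg.adjacency_iou:
                        uf.union(i, j)

        components: dict[int, list[int]] = {}
        for i in range(len(boxes)):
            components.setdefault(uf.find(i), []).append(i)

        # canonical order: each component's minimum (slice_index, y, x)
        keyed = sorted(
            (min((boxes[i].slice_index, boxes[i].y, boxes[i].x) for i in idxs), idxs)
            for _, idxs in components.items()
        )
        lesions: list[Lesion3D] = []
        next_id = 1
        for _, idxs in keyed:
            span = len({boxes[i].slice_index for i in idxs})
            if span < cfg.min_slices:
                continue
            lesion_boxes = sorted(
                (boxes[i].with_lesion_id(next_id) for i in idxs),
                key=lambda b: (b.slice_index, b.y, b.x),
            )
            lesions.append(Lesion3D(lesion_id=next_id, boxes=lesion_boxes))
            next_id += 1
        return lesions


def link_boxes(boxes: list[Box2D], cfg: LinkerConfig | None = None) -> list[Lesion3D]:
    """Link one scan's boxes into numbered multi-slice lesions."""
    cfg = cfg or LinkerConfig()
    return LesionLinker(adjacency_iou=cfg.adjacency_iou, min_slices=cfg.min_slices).transform(boxes)


def lesion_summary(lesions: list[Lesion3D]) -> pd.DataFrame:
    """One row per lesion: id, box count, slice span, largest box area."""
    rows = [
        {
            "lesion_id": l.lesion_id,
            "n_boxes": len(l.boxes),
            "slice_span": l.slice_span,
            "max_box_area": max(b.area for b in l.boxes),
        }
        for l in sorted(lesions, key=lambda l: l.lesion_id)
    ]
    return pd.DataFrame(rows, columns=["lesion_id", "n_boxes", "slice_span", "max_box_area"])
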