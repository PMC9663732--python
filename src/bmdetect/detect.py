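"""Per-slice 2D detection and detector-support utilities.

The detector interface is pluggable: anything that maps a normalized volume
plus brain mask to a list of scored boxes can drive the pipeline.  The
reference implementation, :class:`BlobDetector`, is a deterministic
rule-based detector: per slice it thresholds the normalized intensity inside
the brain, labels connected components, gates them by area and circularity
(``4*pi*area / perimeter**2``, which rejects elongated vessel residues — the
dominant false-positive class for enhancing-lesion detection), and emits the
tight bounding box of each surviving component with score
``mean intensity * circularity``.

:class:`BlobDetectorCV` calibrates the rule parameters by exhaustive grid
search maximizing lesion-level F1 on training scans, standing in for network
training inside the cross-validation harness.

Also here: the geometric training-set augmentations (axis-aligned rotations
and left-right flip, applied identically to image and boxes) and anchor-box
estimation by k-means over (w, h) under the 1 - IoU distance of centred
boxes, the customary prototype-shape construction for single-shot detectors
(seven anchors by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from sklearn.base import BaseEstimator

from .core import Box2D, Lesion3D, Volume3D, iou
from .link import LinkerConfig, link_boxes
from .preprocess import BrainMask

__all__ = [
    "DetectorConfig",
    "AnchorSet",
    "BlobDetector",
    "BlobDetectorCV",
    "NotNormalizedError",
    "detect_slices",
    "augment",
    "estimate_anchors",
    "calibrate_detector",
    "default_detector_grid",
]


class NotNormalizedError(ValueError):
    """The detector requires intensities normalized to [0, 1]."""


@dataclass
class DetectorConfig:
    """Rule parameters of the reference detector.

    Area gates default to the cross-section range implied by the lesion size
    band at 0.9 mm pixels: ``min_area_px=4`` admits the small off-equator
    chord of a 5 mm lesion (about a 2 mm disc), ``max_area_px=800`` bounds
    the equatorial disc of the largest generated lesions.
    """

    intensity_threshold: float = 0.6
    min_area_px: int = 4
    max_area_px: int = 800
    min_circularity: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.intensity_threshold < 1.0):
            raise ValueError("intensity_threshold must lie in (0, 1)")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must not exceed max_area_px")
        if not (0.0 <= self.min_circularity <= 1.0):
            raise ValueError("min_circularity must lie in [0, 1]")


@dataclass
class AnchorSet:
    """k prototype (w, h) box shapes in pixels, sorted by area."""

    anchors: np.ndarray

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(-1, 2)
        if len(self.anchors) < 1 or np.any(self.anchors <= 0):
            raise ValueError("anchors must be a non-empty set of positive (w, h) pairs")

    @property
    def k(self) -> int:
        return len(self.anchors)


def _slice_regions(data: np.ndarray, mask: np.ndarray, threshold: float):
    """Connected-component summaries per slice for one threshold.

    Returns tuples ``(slice, bbox, area, circularity, mean_intensity)``;
    shared by detection and calibration so a parameter grid over the gates
    reuses the labelling work.
    """
    out = []
    for k in range(data.shape[0]):
        binary = (data[k] > threshold) & mask[k]
        if not binary.any():
            continue
        labels = sk_label(binary, connectivity=2)
        for region in regionprops(labels, intensity_image=data[k]):
            perim = region.perimeter
            circ = 1.0 if perim == 0 else min(1.0, 4.0 * math.pi * region.area / perim**2)
            out.append((k, region.bbox, int(region.area), circ, float(region.intensity_mean)))
    return out


def _boxes_from_regions(regions, cfg: DetectorConfig, scan_id: str | None) -> list[Box2D]:
    boxes = []
    for k, (r0, c0, r1, c1), area, circ, mean_int in regions:
        if area < cfg.min_area_px or area > cfg.max_area_px:
            continue
        if circ < cfg.min_circularity:
            continue
        score = max(0.0, min(1.0, mean_int * circ))
        boxes.append(
            Box2D(
                slice_index=k,
                x=float(c0),
                y=float(r0),
                w=float(c1 - c0),
                h=float(r1 - r0),
                score=score,
                scan_id=scan_id,
            )
        )
    boxes.sort(key=lambda b: (b.slice_index, b.y, b.x))
    return boxes


class BlobDetector(BaseEstimator):
    """Deterministic threshold/shape-gate detector over normalized slices."""

    def __init__(
        self,
        intensity_threshold: float = 0.6,
        min_area_px: int = 4,
        max_area_px: int = 800,
        min_circularity: float = 0.4,
    ):
        self.intensity_threshold = intensity_threshold
        self.min_area_px = min_area_px
        self.max_area_px = max_area_px
        self.min_circularity = min_circularity

    @property
    def config(self) -> DetectorConfig:
        return DetectorConfig(
            intensity_threshold=self.intensity_threshold,
            min_area_px=self.min_area_px,
            max_area_px=self.max_area_px,
            min_circularity=self.min_circularity,
        )

    def fit(self, X=None, y=None):  # rule-based; nothing to estimate
        return self

    def predict(self, v: Volume3D, m: BrainMask) -> list[Box2D]:
        cfg = self.config  # validates parameters
        data = np.asarray(v.data)
        if data.min() < -1e-6 or data.max() > 1.0 + 1e-6:
            raise NotNormalizedError(
                "detector input must be normalized to [0, 1]; run normalize_slices first"
            )
        regions = _slice_regions(data, m.mask, cfg.intensity_threshold)
        return _boxes_from_regions(regions, cfg, v.scan_id or None)


def detect_slices(v: Volume3D, m: BrainMask, cfg: DetectorConfig | None = None) -> list[Box2D]:
    """Run the reference detector on every slice of a normalized volume."""
    cfg = cfg or DetectorConfig()
    return BlobDetector(**dataclass_asdict(cfg)).predict(v, m)


def dataclass_asdict(cfg) -> dict:
    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(
    image: np.ndarray,
    boxes: list[Box2D],
    rot: int = 0,
    flip_lr: bool = False,
) -> tuple[np.ndarray, list[Box2D]]:
    """Rotate by a multiple of 90 degrees, then optionally flip left-right.

    The image transform is ``np.rot90`` (counterclockwise in array axes)
    followed by ``np.fliplr``; each box is mapped by the same isometry, e.g.
    a 180-degree rotation in a WxH image sends ``(x, y, w, h)`` to
    ``(W-x-w, H-y-h, w, h)``.
    """
    if rot not in (0, 90, 180, 270):
        raise ValueError(f"rot must be one of 0, 90, 180, 270; got {rot}")
    if image.ndim != 2:
        raise ValueError("augment expects a 2D image")
    H, W = image.shape
    k = rot // 90
    out = np.rot90(image, k)
    mapped = []
    for b in boxes:
        if b.x2 > W + 1e-9 or b.y2 > H + 1e-9:
            raise ValueError(f"box {b} exceeds image bounds {W}x{H}")
        if k == 0:
            x, y, w, h = b.x, b.y, b.w, b.h
        elif k == 1:
            x, y, w, h = b.y, W - b.x - b.w, b.h, b.w
        elif k == 2:
            x, y, w, h = W - b.x - b.w, H - b.y - b.h, b.w, b.h
        else:  # k == 3
            x, y, w, h = H - b.y - b.h, b.x, b.h, b.w
        Wp = out.shape[1]
        if flip_lr:
            x = Wp - x - w
        mapped.append(replace(b, x=x, y=y, w=w, h=h))
    if flip_lr:
        out = np.fliplr(out)
    return np.ascontiguousarray(out), mapped


# ---------------------------------------------------------------------------
# Anchor estimation
# ---------------------------------------------------------------------------

def _wh_iou_dist(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """1 - IoU between centred boxes; shape (n_boxes, n_anchors)."""
    inter = np.minimum(wh[:, None, 0], anchors[None, :, 0]) * np.minimum(
        wh[:, None, 1], anchors[None, :, 1]
    )
    union = (wh[:, 0] * wh[:, 1])[:, None] + (anchors[:, 0] * anchors[:, 1])[None, :] - inter
    return 1.0 - inter / union


def estimate_anchors(boxes: list[Box2D], k: int = 7, seed: int = 0) -> AnchorSet:
    """k-means over (w, h) under the 1 - IoU distance of centred boxes.

    Initialization is a seeded farthest-point sweep (first centre drawn at
    random, each further centre the box maximizing its distance to the
    chosen set), then Lloyd iterations with arithmetic-mean centroids.
    Deterministic for a fixed seed; anchors are returned sorted by area.
    """
    if len(boxes) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(boxes)}")
    wh = np.array([[b.w, b.h] for b in boxes], dtype=float)
    rng = np.random.default_rng(seed)

    centers = wh[[int(rng.integers(len(wh)))]]
    while len(centers) < k:
        d = _wh_iou_dist(wh, centers).min(axis=1)
        centers = np.vstack([centers, wh[int(d.argmax())]])

    assign = np.full(len(wh), -1)
    for _ in range(100):
        new_assign = _wh_iou_dist(wh, centers).argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if sel.any():
                centers[j] = wh[sel].mean(axis=0)
            else:  # re-seed an empty cluster with the worst-served box
                d = _wh_iou_dist(wh, centers).min(axis=1)
                centers[j] = wh[int(d.argmax())]
    order = np.argsort(centers[:, 0] * centers[:, 1], kind="stable")
    return AnchorSet(anchors=centers[order])


# ---------------------------------------------------------------------------
# Calibration (stands in for detector training)
# ---------------------------------------------------------------------------

def default_detector_grid() -> list[DetectorConfig]:
    """Small exhaustive grid over the threshold and the circularity gate."""
    return [
        DetectorConfig(intensity_threshold=t, min_circularity=c)
        for t in (0.55, 0.65, 0.75)
        for c in (0.3, 0.45)
    ]


def calibrate_detector(
    train_scans: list[tuple[Volume3D, BrainMask, list[Lesion3D]]],
    grid: list[DetectorConfig] | None = None,
    linker: LinkerConfig | None = None,
    match_iou: float = 0.5,
) -> DetectorConfig:
    """Exhaustive grid search maximizing pooled lesion-level F1.

    Ties are broken by lower false positives per scan, then lower intensity
    threshold; the result is deterministic for fixed inputs.
    """
    from .evaluate import EvalConfig, f1_score, match_lesions  # local: avoid cycle

    if not train_scans:
        raise ValueError("calibration requires at least one training scan")
    grid = grid if grid is not None else default_detector_grid()
    if not grid:
        raise ValueError("empty detector grid")
    linker = linker or LinkerConfig()
    eval_cfg = EvalConfig(match_iou=match_iou)

    # group configs by threshold so component labelling is done once per scan
    by_thr: dict[float, list[DetectorConfig]] = {}
    for cfg in grid:
        by_thr.setdefault(cfg.intensity_threshold, []).append(cfg)

    results = []
    for thr in sorted(by_thr):
        region_cache = [
            _slice_regions(np.asarray(v.data), m.mask, thr) for v, m, _ in train_scans
        ]
        for cfg in by_thr[thr]:
            tp = fn = fp = 0
            for (v, m, gt_lesions), regions in zip(train_scans, region_cache):
                pred = link_boxes(_boxes_from_regions(regions, cfg, v.scan_id or None), linker)
                counts = match_lesions(gt_lesions, pred, eval_cfg)
                tp += counts.tp
                fn += counts.fn
                fp += counts.fp
            denom = 2 * tp + fn + fp
            f1 = 0.0 if denom == 0 else f1_score(tp, fp, fn)
            fp_avg = fp / len(train_scans)
            results.append(((-f1, fp_avg, cfg.intensity_threshold, cfg.min_circularity,
                             cfg.min_area_px, cfg.max_area_px), cfg))
    results.sort(key=lambda r: r[0])
    return results[0][1]


class BlobDetectorCV(BaseEstimator):
    """Grid-calibrated detector with a fit/predict surface.

    ``fit`` expects a list of ``(normalized_volume, brain_mask, gt_lesions)``
    training scans and selects the grid configuration maximizing pooled
    lesion-level F1; fitted attributes are ``best_config_``,
    ``best_estimator_`` and ``best_params_``.
    """

    def __init__(self, grid: list[DetectorConfig] | None = None,
                 adjacency_iou: float = 0.3, min_slices: int = 2,
                 match_iou: float = 0.5):
        self.grid = grid
        self.adjacency_iou = adjacency_iou
        self.min_slices = min_slices
        self.match_iou = match_iou

    def fit(self, X, y=None):
        linker = LinkerConfig(adjacency_iou=self.adjacency_iou, min_slices=self.min_slices)
        self.best_config_ = calibrate_detector(
            X, grid=self.grid, linker=linker, match_iou=self.match_iou
        )
        self.best_params_ = dataclass_asdict(self.best_config_)
        self.best_estimator_ = BlobDetector(**self.best_params_)
        return self

    def predict(self, v: Volume3D, m: BrainMask) -> list[Box2D]:
        if not hasattr(self, "best_estimator_"):
            raise RuntimeError("BlobDetectorCV is not fitted")
        return self.best_estimator_.predict(v, m)
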