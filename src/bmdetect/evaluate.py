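"""Lesion-level matching and the detection metric suite.

A predicted lesion certifies a ground-truth lesion when, on at least one
slice, a predicted box and a ground-truth box of those lesions overlap with
IoU above the matching threshold (default 0.5) — the "one slice of the whole
lesion counts" rule, since flagging any part of a lesion is what helps the
reading radiologist.  Matching is one-to-one, greedy by descending
best-slice IoU, so a single prediction cannot certify two lesions.

Metrics (all per lesion, not per box)::

    sensitivity (TPR) = TP / (TP + FN)
    precision   (PPV) = TP / (TP + FP)
    F1                = 2*TP / (2*TP + FN + FP)
    FP_avg            = FP_total / N scans

Counts are integers and the rates are exact rationals internally; rounding
to two decimals happens only when a report is rendered.  Scans without any
ground truth (a normal cohort) have no labels, so only FP_avg is defined
for them.  A reading-time summary (per-rater percent reduction and the
paired t-test) is included as a reporting utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from scipy import stats

from .core import Lesion3D, iou

__all__ = [
    "EvalConfig",
    "ScanCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "match_lesions",
    "sensitivity",
    "precision",
    "f1_score",
    "fp_avg",
    "pool_folds",
    "evaluate_normals",
    "paired_reduction",
    "mean_percent_reduction",
    "reading_time_ttest",
]


class UndefinedMetricError(ValueError):
    """A rate's denominator is zero; the metric is undefined, not 0."""


@dataclass
class EvalConfig:
    """``one_slice_tp=True`` scores a hit on any one slice as a true
    positive; ``False`` demands a hit on every slice of the lesion."""

    match_iou: float = 0.5
    one_slice_tp: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.match_iou <= 1.0):
            raise ValueError("match_iou must lie in [0, 1]")


@dataclass
class ScanCounts:
    scan_id: str
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    """Pooled metrics plus per-fold breakdowns (all percentages 0-100)."""

    tp: int
    fn: int
    fp: int
    n_scans: int
    sensitivity: float | None
    precision: float | None
    f1: float | None
    f1_tablestyle: float | None  # TPR*PPV/(TPR+PPV): half of F1, as some
    # reports tabulate it; emitted alongside, clearly labelled
    fp_avg: float | None
    fp_avg_normal: float | None = None
    per_fold: dict = field(default_factory=dict)


def _check_linked(lesions: list[Lesion3D], what: str) -> None:
    for l in lesions:
        for b in l.boxes:
            if b.lesion_id is None:
                raise ValueError(f"{what} lesion contains an unlinked box (missing lesion_id)")


def _pair_score(gt: Lesion3D, pred: Lesion3D, cfg: EvalConfig) -> float:
    """Best (or, without the one-slice rule, worst) per-slice box IoU."""
    per_slice = []
    for s in gt.slices:
        pred_here = pred.boxes_on(s)
        gt_here = gt.boxes_on(s)
        best = 0.0
        for g in gt_here:
            for p in pred_here:
                best = max(best, iou(g, p))
        per_slice.append(best)
    if cfg.one_slice_tp:
        return max(per_slice) if per_slice else 0.0
    return min(per_slice) if per_slice else 0.0


def match_lesions(
    gt: list[Lesion3D],
    pred: list[Lesion3D],
    cfg: EvalConfig | None = None,
    scan_id: str = "",
) -> ScanCounts:
    """Greedy one-to-one lesion matching; returns the scan's TP/FN/FP."""
    cfg = cfg or EvalConfig()
    _check_linked(gt, "ground-truth")
    _check_linked(pred, "predicted")

    pairs = []
    for g in gt:
        for p in pred:
            score = _pair_score(g, p, cfg)
            if score > cfg.match_iou:
                pairs.append((score, g.lesion_id, p.lesion_id))
    # descending score; deterministic tie-break on the lesion numbers
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    for score, gid, pid in pairs:
        if gid in matched_gt or pid in matched_pred:
            continue
        matched_gt.add(gid)
        matched_pred.add(pid)

    tp = len(matched_gt)
    return ScanCounts(scan_id=scan_id, tp=tp, fn=len(gt) - tp, fp=len(pred) - len(matched_pred))


# ---------------------------------------------------------------------------
# Metric arithmetic
# ---------------------------------------------------------------------------

def _pct(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return float(100 * Fraction(num, den))


def sensitivity(tp: int, fn: int) -> float:
    """True-positive rate as a percentage: 100*TP/(TP+FN)."""
    return _pct(tp, tp + fn, "sensitivity")


def precision(tp: int, fp: int) -> float:
    """Positive predictive value as a percentage: 100*TP/(TP+FP)."""
    return _pct(tp, tp + fp, "precision")


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 as a percentage: 100*2*TP/(2*TP+FN+FP)."""
    return _pct(2 * tp, 2 * tp + fn + fp, "f1")


def fp_avg(fp_total: int, n_scans: int) -> float:
    """False positives per scan."""
    if n_scans <= 0:
        raise UndefinedMetricError("fp_avg undefined for zero scans")
    return float(Fraction(fp_total, n_scans))


def _metrics_or_none(tp: int, fn: int, fp: int, n_scans: int) -> dict:
    out: dict = {"tp": tp, "fn": fn, "fp": fp, "n_scans": n_scans}
    for key, fun, args in (
        ("sensitivity", sensitivity, (tp, fn)),
        ("precision", precision, (tp, fp)),
        ("f1", f1_score, (tp, fp, fn)),
    ):
        try:
            out[key] = fun(*args)
        except UndefinedMetricError:
            out[key] = None
    out["f1_tablestyle"] = None if out["f1"] is None else out["f1"] / 2.0
    out["fp_avg"] = None if n_scans == 0 else fp_avg(fp, n_scans)
    out["valid"] = all(out[k] is not None for k in ("sensitivity", "precision", "f1"))
    return out


def pool_folds(fold_counts: dict[object, list[ScanCounts]]) -> MetricsReport:
    """Per-fold metrics plus pooled metrics from summed TP/FN/FP.

    Pooling sums raw counts across all scans of all folds (the "overall"
    row of a cross-validation table), so it is invariant to fold order.
    """
    if not fold_counts:
        raise ValueError("pool_folds requires at least one fold")
    per_fold = {}
    tot_tp = tot_fn = tot_fp = tot_n = 0
    for fold in sorted(fold_counts, key=str):
        counts = fold_counts[fold]
        tp = sum(c.tp for c in counts)
        fn = sum(c.fn for c in counts)
        fp = sum(c.fp for c in counts)
        per_fold[fold] = _metrics_or_none(tp, fn, fp, len(counts))
        tot_tp, tot_fn, tot_fp, tot_n = tot_tp + tp, tot_fn + fn, tot_fp + fp, tot_n + len(counts)
    pooled = _metrics_or_none(tot_tp, tot_fn, tot_fp, tot_n)
    return MetricsReport(
        tp=tot_tp,
        fn=tot_fn,
        fp=tot_fp,
        n_scans=tot_n,
        sensitivity=pooled["sensitivity"],
        precision=pooled["precision"],
        f1=pooled["f1"],
        f1_tablestyle=pooled["f1_tablestyle"],
        fp_avg=pooled["fp_avg"],
        per_fold=per_fold,
    )


def evaluate_normals(pred_lesions_per_scan: list[list[Lesion3D]] | list[int]) -> float:
    """FP per scan on a lesion-free cohort: every prediction is an FP."""
    if len(pred_lesions_per_scan) == 0:
        raise UndefinedMetricError("fp_avg_normal undefined for zero scans")
    fps = [p if isinstance(p, int) else len(p) for p in pred_lesions_per_scan]
    return fp_avg(sum(fps), len(fps))


# ---------------------------------------------------------------------------
# Reading-time summary
# ---------------------------------------------------------------------------

def paired_reduction(times_without: list[float], times_with: list[float]) -> float:
    """One rater's percent reduction: 100*(mean_without-mean_with)/mean_without."""
    if not times_without or not times_with:
        raise ValueError("need non-empty reading-time lists")
    if min(times_without) <= 0 or min(times_with) <= 0:
        raise ValueError("reading times must be positive")
    mw = sum(times_without) / len(times_without)
    mwith = sum(times_with) / len(times_with)
    return 100.0 * (mw - mwith) / mw


def mean_percent_reduction(reductions: list[float]) -> float:
    """Arithmetic mean of per-rater percent reductions."""
    if not reductions:
        raise ValueError("need at least one rater")
    return sum(reductions) / len(reductions)


def reading_time_ttest(times_without: list[float], times_with: list[float]):
    """Two-sided paired t-test on per-case reading times; (statistic, p)."""
    res = stats.ttest_rel(times_without, times_with)
    return float(res.statistic), float(res.pvalue)


def round_report(report: MetricsReport, ndigits: int = 2) -> dict:
    """Render a report with table-style rounding (2 decimal places)."""

    def rnd(x):
        return None if x is None else round(x, ndigits)

    def fold_view(d):
        return {
            k: (rnd(v) if isinstance(v, float) else v)
            for k, v in d.items()
        }

    return {
        "tp": report.tp,
        "fn": report.fn,
        "fp": report.fp,
        "n_scans": report.n_scans,
        "sensitivity": rnd(report.sensitivity),
        "precision": rnd(report.precision),
        "f1": rnd(report.f1),
        "f1_tablestyle": rnd(report.f1_tablestyle),
        "fp_avg": rnd(report.fp_avg),
        "fp_avg_normal": rnd(report.fp_avg_normal),
        "per_fold": {str(k): fold_view(v) for k, v in report.per_fold.items()},
    }
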