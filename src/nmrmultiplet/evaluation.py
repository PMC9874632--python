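"""Two-level evaluation of point-wise multiplet predictions.

Point-wise: an 8-class confusion matrix over spectral points, with
one-vs-rest accuracy, precision, recall and F1 per class.

Object-wise: maximal runs of identically labeled points become region
predictions whose confidence is the mean softmax probability of the
run's class.  Predictions are ranked by confidence, matched greedily
one-to-one to same-class ground-truth regions by 1-D intersection over
union (IOU), and summarized by all-point interpolated average precision
(AP) at an IOU threshold, plus the mean over classes (mAP).  The
object-wise view penalizes fragmented predictions that point-wise
accuracy barely notices.

A third, peak-level protocol scores an expert peak list against a
predicted label vector: each annotated peak is counted at the label of
its nearest grid point (baseline counts as "unassigned").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import N_CLASSES, SpectrumSegment

BASELINE = 0


# ---------------------------------------------------------------------------
# point-wise
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("counts must be a square nonnegative matrix")
        self.counts = c.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def row_normalized(self) -> np.ndarray:
        """Rows divided by their ground-truth support; zero-support rows are NaN."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / sums
        out[np.repeat(sums == 0, self.n_classes, axis=1)] = np.nan
        return out

    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass
class ClassMetrics:
    """One-vs-rest counts and derived rates for a single class.

    Ratios with zero denominators are NaN ("not a value"), never
    silently coerced to 0.
    """

    class_id: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else math.nan

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else math.nan

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)


def pointwise_confusion(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES
) -> ConfusionMatrix:
    """``counts[i, j]`` = number of points of true class ``i`` predicted as ``j``."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = np.bincount(y_true * n_classes + y_pred, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def class_metrics(cm: ConfusionMatrix, class_id: int) -> ClassMetrics:
    """One-vs-rest TP/FP/FN/TN and rates for ``class_id`` from a confusion matrix."""
    c = cm.counts
    tp = int(c[class_id, class_id])
    fp = int(c[:, class_id].sum() - tp)
    fn = int(c[class_id, :].sum() - tp)
    tn = int(c.sum() - tp - fp - fn)
    return ClassMetrics(class_id=class_id, tp=tp, fp=fp, fn=fn, tn=tn)


def all_class_metrics(cm: ConfusionMatrix) -> list[ClassMetrics]:
    return [class_metrics(cm, c) for c in range(cm.n_classes)]


# ---------------------------------------------------------------------------
# object-wise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionPrediction:
    """A maximal run of identically labeled points: class, half-open span, confidence."""

    class_id: int
    span: tuple[int, int]
    confidence: float = 1.0

    def __post_init__(self):
        if self.span[1] <= self.span[0]:
            raise ValueError(f"empty span {self.span}")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class PRCurve:
    """Ranked precision-recall points for one class at one IOU threshold."""

    class_id: int
    iou_threshold: float
    recalls: np.ndarray
    precisions: np.ndarray
    n_truths: int
    ap: float = field(init=False)

    def __post_init__(self):
        self.ap = average_precision(self.recalls, self.precisions)


def label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels as (label, start, stop) with half-open spans."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def extract_regions(prediction) -> list[RegionPrediction]:
    """Region predictions from a :class:`PredictionResult`.

    Baseline runs are excluded; the confidence of a run of class ``l``
    is the arithmetic mean of the softmax probability of ``l`` over the
    run's points.
    """
    labels = np.asarray(prediction.labels)
    probs = np.asarray(prediction.probabilities)
    out = []
    for lab, a, b in label_runs(labels):
        if lab == BASELINE:
            continue
        out.append(
            RegionPrediction(
                class_id=lab, span=(a, b), confidence=float(probs[a:b, lab].mean())
            )
        )
    return out


def truth_regions(labels: np.ndarray) -> list[RegionPrediction]:
    """Ground-truth regions from a label vector (confidence fixed at 1)."""
    return [
        RegionPrediction(class_id=lab, span=(a, b))
        for lab, a, b in label_runs(np.asarray(labels))
        if lab != BASELINE
    ]


def region_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    """1-D intersection over union of two half-open index intervals."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("intervals must be nonempty")
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


def match_and_curve(
    preds: list[RegionPrediction],
    truths: list[RegionPrediction],
    iou_threshold: float,
    class_id: int | None = None,
    recall_denominator: str = "truths",
) -> PRCurve:
    """Confidence-ranked greedy one-to-one matching and the PR curve it traces.

    Predictions (optionally restricted to ``class_id``) are sorted by
    confidence descending (ties by span start).  Each is a true positive
    iff its best IOU against a same-class, not-yet-matched ground-truth
    region reaches ``iou_threshold``; otherwise a false positive.
    ``recall_denominator`` selects the standard convention ("truths") or
    the literal total-prediction count ("predictions").
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    if recall_denominator not in ("truths", "predictions"):
        raise ValueError("recall_denominator must be 'truths' or 'predictions'")
    if class_id is not None:
        preds = [p for p in preds if p.class_id == class_id]
        truths = [t for t in truths if t.class_id == class_id]
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, preds[i].span[0]))
    matched = [False] * len(truths)
    tp_flags = []
    for i in order:
        p = preds[i]
        best, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if matched[j] or t.class_id != p.class_id:
                continue
            iou = region_iou(p.span, t.span)
            if iou > best:
                best, best_j = iou, j
        if best_j >= 0 and best >= iou_threshold:
            matched[best_j] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    cum_tp = np.cumsum(tp_flags) if tp_flags else np.array([])
    k = np.arange(1, len(tp_flags) + 1)
    denom = len(truths) if recall_denominator == "truths" else len(tp_flags)
    recalls = cum_tp / denom if denom else cum_tp * 0.0
    precisions = cum_tp / k if len(k) else np.array([])
    return PRCurve(
        class_id=class_id if class_id is not None else -1,
        iou_threshold=iou_threshold,
        recalls=np.asarray(recalls, dtype=float),
        precisions=np.asarray(precisions, dtype=float),
        n_truths=len(truths),
    )


def average_precision(recalls: np.ndarray, precisions: np.ndarray) -> float:
    """All-point interpolated AP: sum over steps of dR times max precision at recall >= R."""
    recalls = np.asarray(recalls, dtype=float)
    precisions = np.asarray(precisions, dtype=float)
    if recalls.size == 0:
        return 0.0
    ap = 0.0
    prev_r = 0.0
    for n in range(len(recalls)):
        r = recalls[n]
        if r > prev_r:
            p_interp = precisions[n:].max()  # recalls are nondecreasing along the ranking
            ap += (r - prev_r) * p_interp
            prev_r = r
    return float(ap)


def mean_ap(curves: list[PRCurve]) -> float:
    """Unweighted mean AP over classes that have at least one ground-truth region."""
    aps = [c.ap for c in curves if c.n_truths > 0]
    if not aps:
        return math.nan
    return float(np.mean(aps))


def objectwise_evaluation(
    predictions,
    truths_labels,
    iou_thresholds=(0.5, 0.75),
    recall_denominator: str = "truths",
) -> dict:
    """Per-class PR curves, APs and mAP over a collection of segments.

    ``predictions`` is a sequence of :class:`PredictionResult`-like
    objects, ``truths_labels`` the matching ground-truth label vectors.
    Regions from all segments are pooled (spans offset per segment so
    regions from different segments never overlap).
    """
    all_preds: list[RegionPrediction] = []
    all_truths: list[RegionPrediction] = []
    offset = 0
    for pred, y in zip(predictions, truths_labels):
        n = len(np.asarray(y))
        for r in extract_regions(pred):
            all_preds.append(
                RegionPrediction(r.class_id, (r.span[0] + offset, r.span[1] + offset), r.confidence)
            )
        for r in truth_regions(y):
            all_truths.append(
                RegionPrediction(r.class_id, (r.span[0] + offset, r.span[1] + offset))
            )
        offset += n + 1
    report: dict = {"thresholds": {}}
    for t in iou_thresholds:
        curves = [
            match_and_curve(all_preds, all_truths, t, class_id=c, recall_denominator=recall_denominator)
            for c in range(1, N_CLASSES)
        ]
        report["thresholds"][t] = {
            "curves": curves,
            "ap_per_class": {c.class_id: c.ap for c in curves if c.n_truths > 0},
            "map": mean_ap(curves),
        }
    return report


# ---------------------------------------------------------------------------
# peak-level protocol (expert peak lists)
# ---------------------------------------------------------------------------


def peak_level_confusion(
    peak_positions_hz: np.ndarray,
    peak_classes: np.ndarray,
    axis_hz: np.ndarray,
    predicted_labels: np.ndarray,
) -> ConfusionMatrix:
    """Score an annotated peak list against a predicted label vector.

    Each peak contributes one count at (true class, predicted label of
    the nearest grid point).  Row/column 0 represents "unassigned"
    (baseline) predictions; true classes are 1..7.
    """
    pos = np.asarray(peak_positions_hz, dtype=float)
    cls = np.asarray(peak_classes, dtype=int)
    axis = np.asarray(axis_hz, dtype=float)
    if pos.shape != cls.shape:
        raise ValueError("positions and classes must align")
    if cls.size and (cls.min() < 1 or cls.max() >= N_CLASSES):
        raise ValueError("peak classes must lie in 1..7")
    lo, hi = axis.min(), axis.max()
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for p, c in zip(pos, cls):
        if not lo <= p <= hi:
            raise ValueError(f"peak at {p:.3f} Hz lies outside the axis [{lo:.3f}, {hi:.3f}]")
        idx = int(np.argmin(np.abs(axis - p)))
        counts[c, int(predicted_labels[idx])] += 1
    return ConfusionMatrix(counts)


def segment_peak_table(segment: SpectrumSegment) -> tuple[np.ndarray, np.ndarray]:
    """Simulator-derived peak list (positions Hz, classes) for a synthetic segment."""
    positions, classes = [], []
    for spec in segment.multiplets():
        for c in spec.peak_centers():
            positions.append(float(c))
            classes.append(spec.class_id)
    return np.asarray(positions), np.asarray(classes, dtype=int)
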