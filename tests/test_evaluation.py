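"""Evaluation suite vs independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from nmrmultiplet.classifier import PredictionResult
from nmrmultiplet.evaluation import (
    RegionPrediction,
    all_class_metrics,
    average_precision,
    class_metrics,
    extract_regions,
    label_runs,
    match_and_curve,
    mean_ap,
    peak_level_confusion,
    pointwise_confusion,
    region_iou,
    truth_regions,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------


def brute_confusion(y, yhat, n=8):
    c = np.zeros((n, n), dtype=int)
    for a, b in zip(y, yhat):
        c[a][b] += 1
    return c


def brute_class_counts(y, yhat, cls):
    tp = sum(1 for a, b in zip(y, yhat) if a == cls and b == cls)
    fp = sum(1 for a, b in zip(y, yhat) if a != cls and b == cls)
    fn = sum(1 for a, b in zip(y, yhat) if a == cls and b != cls)
    tn = sum(1 for a, b in zip(y, yhat) if a != cls and b != cls)
    return tp, fp, fn, tn


def brute_iou(a, b):
    sa = set(range(*a))
    sb = set(range(*b))
    return len(sa & sb) / len(sa | sb)


def brute_ap(tp_flags, n_truths):
    """Exhaustive all-point interpolation over the ranked TP/FP list."""
    if not tp_flags or n_truths == 0:
        return 0.0
    cum = list(itertools.accumulate(int(f) for f in tp_flags))
    recalls = [c / n_truths for c in cum]
    precisions = [c / (i + 1) for i, c in enumerate(cum)]
    ap, prev = 0.0, 0.0
    for i, r in enumerate(recalls):
        if r > prev:
            ap += (r - prev) * max(precisions[i:])
            prev = r
    return ap


# ---------------------------------------------------------------------------
# point-wise
# ---------------------------------------------------------------------------


class TestPointwiseConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([0, 1, 2, 3, 3, 7])
        cm = pointwise_confusion(y, y)
        assert np.all(cm.counts == np.diag(np.bincount(y, minlength=8)))
        for m in all_class_metrics(cm):
            if m.tp + m.fn > 0:
                assert m.precision == m.recall == m.f1 == 1.0

    def test_hand_example(self):
        cm = pointwise_confusion([0, 1, 1], [0, 1, 0])
        assert cm.counts[1, 1] == 1 and cm.counts[1, 0] == 1 and cm.counts[0, 0] == 1
        m = class_metrics(cm, 1)
        assert m.precision == 1.0
        assert m.recall == 0.5
        assert m.f1 == pytest.approx(2 / 3)

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 8, 137)
        yhat = rng.integers(0, 8, 137)
        cm = pointwise_confusion(y, yhat)
        assert cm.counts.sum() == 137
        for m in all_class_metrics(cm):
            assert m.tp + m.fp + m.fn + m.tn == 137

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pointwise_confusion([0, 1], [0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pointwise_confusion([0, 9], [0, 1])

    def test_zero_support_is_nan_not_zero(self):
        cm = pointwise_confusion([0, 0], [0, 0])
        m = class_metrics(cm, 5)
        assert math.isnan(m.precision) and math.isnan(m.recall)
        assert np.isnan(cm.row_normalized()[5]).all()

    def test_micro_consistency_random(self):
        """Summed per-class TP / total equals overall accuracy."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 8, 500)
        yhat = rng.integers(0, 8, 500)
        cm = pointwise_confusion(y, yhat)
        tp_sum = sum(class_metrics(cm, c).tp for c in range(8))
        assert tp_sum / 500 == pytest.approx(cm.overall_accuracy())

    def test_against_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            y = rng.integers(0, 8, n)
            yhat = rng.integers(0, 8, n)
            cm = pointwise_confusion(y, yhat)
            np.testing.assert_array_equal(cm.counts, brute_confusion(y, yhat))
            for cls in range(8):
                m = class_metrics(cm, cls)
                assert (m.tp, m.fp, m.fn, m.tn) == brute_class_counts(y, yhat, cls)


# ---------------------------------------------------------------------------
# object-wise
# ---------------------------------------------------------------------------


def _prediction_from_labels(labels, confidence_rows=None):
    labels = np.asarray(labels)
    probs = np.zeros((len(labels), 8))
    probs[np.arange(len(labels)), labels] = 1.0
    if confidence_rows is not None:
        probs = confidence_rows
    return PredictionResult(probabilities=probs, labels=labels)


class TestRegions:
    def test_all_baseline_yields_no_regions(self):
        pred = _prediction_from_labels([0, 0, 0, 0])
        assert extract_regions(pred) == []

    def test_confidence_is_mean_softmax(self):
        labels = np.array([0, 3, 3, 0])
        probs = np.full((4, 8), 0.01)
        probs[1, 3], probs[2, 3] = 0.6, 0.8
        pred = PredictionResult(probabilities=probs, labels=labels)
        (region,) = extract_regions(pred)
        assert region.class_id == 3
        assert region.span == (1, 3)
        assert region.confidence == pytest.approx(0.7)

    def test_run_length_decomposition(self):
        pred = _prediction_from_labels([1, 1, 0, 2, 2])
        regions = extract_regions(pred)
        assert [(r.class_id, r.span) for r in regions] == [(1, (0, 2)), (2, (3, 5))]

    def test_runs_cover_vector(self):
        labels = np.array([0, 1, 1, 2, 0, 0, 5])
        runs = label_runs(labels)
        assert sum(b - a for _, a, b in runs) == len(labels)


class TestIou:
    def test_identical_is_one(self):
        assert region_iou((3, 9), (3, 9)) == 1.0

    def test_disjoint_is_zero(self):
        assert region_iou((0, 5), (7, 9)) == 0.0

    def test_partial_overlap(self):
        assert region_iou((0, 10), (5, 15)) == pytest.approx(5 / 15)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            region_iou((5, 5), (0, 3))

    def test_against_set_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = tuple(sorted(rng.integers(0, 40, 2)))
            b = tuple(sorted(rng.integers(0, 40, 2)))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            assert region_iou(a, b) == pytest.approx(brute_iou(a, b))


class TestMatchingAndAP:
    def test_exact_predictions_perfect_curve(self):
        truths = [RegionPrediction(1, (0, 5)), RegionPrediction(2, (10, 20))]
        preds = [RegionPrediction(1, (0, 5), 0.9), RegionPrediction(2, (10, 20), 0.8)]
        curve = match_and_curve(preds, truths, 0.5)
        np.testing.assert_allclose(curve.precisions, 1.0)
        assert curve.recalls[-1] == 1.0
        assert curve.ap == 1.0

    def test_threshold_flips_tp_to_fp(self):
        truths = [RegionPrediction(1, (0, 10))]
        preds = [RegionPrediction(1, (0, 6), 0.9)]  # IOU 0.6
        assert match_and_curve(preds, truths, 0.5).ap == 1.0
        assert match_and_curve(preds, truths, 0.75).ap == 0.0

    def test_one_to_one_matching(self):
        truths = [RegionPrediction(4, (0, 10))]
        preds = [
            RegionPrediction(4, (0, 10), 0.9),
            RegionPrediction(4, (1, 10), 0.8),
        ]
        curve = match_and_curve(preds, truths, 0.5)
        assert list(np.diff(np.concatenate([[0], curve.recalls * curve.n_truths]))).count(1) == 1

    def test_hand_computed_three_prediction_ap(self):
        """Ranked [TP, FP, TP] with 2 truths: AP = 0.5*1 + 0.5*(2/3)."""
        truths = [RegionPrediction(1, (0, 10)), RegionPrediction(1, (20, 30))]
        preds = [
            RegionPrediction(1, (0, 10), 0.9),   # TP
            RegionPrediction(1, (40, 50), 0.8),  # FP
            RegionPrediction(1, (20, 30), 0.7),  # TP
        ]
        curve = match_and_curve(preds, truths, 0.5)
        assert curve.ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_all_fp_gives_zero_ap(self):
        truths = [RegionPrediction(1, (0, 10))]
        preds = [RegionPrediction(1, (30, 40), 0.9)]
        assert match_and_curve(preds, truths, 0.5).ap == 0.0

    def test_recall_denominator_option(self):
        truths = [RegionPrediction(1, (0, 10)), RegionPrediction(1, (20, 30))]
        preds = [RegionPrediction(1, (0, 10), 0.9)]
        standard = match_and_curve(preds, truths, 0.5, recall_denominator="truths")
        literal = match_and_curve(preds, truths, 0.5, recall_denominator="predictions")
        assert standard.recalls[-1] == 0.5
        assert literal.recalls[-1] == 1.0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_and_curve([], [], 0.0)

    def test_ap_against_exhaustive_oracle(self):
        """Random ranked TP/FP lists: AP matches the naive construction to 1e-9."""
        rng = np.random.default_rng(4)
        for _ in range(500):
            n_truths = int(rng.integers(1, 8))
            flags = list(rng.random(int(rng.integers(1, 12))) < 0.5)
            flags = [f and sum(flags[:i]) < n_truths for i, f in enumerate(flags)]
            cum = np.cumsum(flags)
            recalls = cum / n_truths
            precisions = cum / np.arange(1, len(flags) + 1)
            assert average_precision(recalls, precisions) == pytest.approx(
                brute_ap(flags, n_truths), abs=1e-9
            )

    def test_mean_ap_skips_empty_classes(self):
        curves = [
            match_and_curve(
                [RegionPrediction(1, (0, 5), 0.9)], [RegionPrediction(1, (0, 5))], 0.5, class_id=1
            ),
            match_and_curve([], [], 0.5, class_id=2),
        ]
        assert mean_ap(curves) == 1.0

    def test_fragmentation_hurts_ap_more_than_accuracy(self):
        """Splitting a region into two classes tanks AP but barely moves accuracy."""
        y = np.zeros(200, dtype=int)
        y[50:100] = 3
        intact = _prediction_from_labels(y)
        frag_labels = y.copy()
        frag_labels[75:100] = 4  # half the region drifts to another class
        frag = _prediction_from_labels(frag_labels)

        cm_ok = pointwise_confusion(y, intact.labels)
        cm_frag = pointwise_confusion(y, frag_labels)
        assert cm_frag.overall_accuracy() >= 0.85  # point-wise barely cares

        truths = truth_regions(y)
        ap_ok = match_and_curve(extract_regions(intact), truths, 0.75, class_id=3).ap
        ap_frag = match_and_curve(extract_regions(frag), truths, 0.75, class_id=3).ap
        assert ap_ok == 1.0
        assert ap_frag < ap_ok  # strictly lower object-wise score
        assert cm_ok.overall_accuracy() - cm_frag.overall_accuracy() <= 0.15


# ---------------------------------------------------------------------------
# peak-level protocol
# ---------------------------------------------------------------------------


class TestPeakLevel:
    def test_peaks_in_correct_regions_are_diagonal(self):
        axis = np.arange(100, dtype=float)
        labels = np.zeros(100, dtype=int)
        labels[10:20] = 2
        cm = peak_level_confusion([12.0, 18.0], [2, 2], axis, labels)
        assert cm.counts[2, 2] == 2 and cm.counts.sum() == 2

    def test_baseline_point_counts_unassigned(self):
        axis = np.arange(100, dtype=float)
        labels = np.zeros(100, dtype=int)
        cm = peak_level_confusion([50.0], [3], axis, labels)
        assert cm.counts[3, 0] == 1  # unassigned, not misclassified

    def test_peak_outside_axis_rejected(self):
        axis = np.arange(100, dtype=float)
        with pytest.raises(ValueError, match="outside"):
            peak_level_confusion([150.0], [1], axis, np.zeros(100, dtype=int))
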