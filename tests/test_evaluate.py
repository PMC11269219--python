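"""Detection metrics, complexity formulas, and agreement regression."""

import itertools

import numpy as np
import pytest

from radiclemorph import (
    DetectionRecord,
    agreement_analysis,
    average_precision,
    box_iou,
    conv_complexity,
    map_range,
    mask_iou,
)
from radiclemorph.evaluate import MAP_THRESHOLDS


class TestIoU:
    def test_identical_boxes(self):
        assert box_iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_half_overlapping_unit_squares(self):
        assert box_iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            box_iou((0, 0, 0, 1), (0, 0, 1, 1))

    def test_mask_iou_both_empty_is_one(self):
        assert mask_iou(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_mask_iou_half(self):
        a = np.zeros((2, 2)); a[0] = 1
        b = np.ones((2, 2))
        assert mask_iou(a, b) == pytest.approx(0.5)


def brute_force_ap(preds, truths, thr):
    """Enumerate the PR curve by hand and integrate the monotone envelope."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    matched = set()
    points = []
    tp = fp = 0
    for i in order:
        best, bj = 0.0, None
        for j, t in enumerate(truths):
            if j in matched:
                continue
            iou = box_iou(preds[i].box, t.box)
            if iou > best:
                best, bj = iou, j
        if bj is not None and best >= thr:
            matched.add(bj)
            tp += 1
        else:
            fp += 1
        points.append((tp / (tp + fp), tp / len(truths)))
    ap = 0.0
    prev_r = 0.0
    for idx, (p, r) in enumerate(points):
        env = max(pp for pp, rr in points[idx:])
        ap += (r - prev_r) * env
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_predictions(self):
        truths = [DetectionRecord((0, 0, 2, 2)), DetectionRecord((5, 5, 8, 8))]
        preds = [DetectionRecord(t.box, confidence=1.0) for t in truths]
        assert average_precision(preds, truths, 0.5) == pytest.approx(1.0)

    def test_no_predictions_zero_ap(self):
        assert average_precision([], [DetectionRecord((0, 0, 1, 1))], 0.5) == 0.0

    def test_three_preds_two_truths_matches_brute_force(self):
        truths = [DetectionRecord((0, 0, 4, 4)), DetectionRecord((10, 10, 14, 14))]
        preds = [
            DetectionRecord((0, 0, 4, 4), confidence=0.9),
            DetectionRecord((20, 20, 24, 24), confidence=0.8),  # unmatchable
            DetectionRecord((10, 10, 14, 13), confidence=0.7),
        ]
        for thr in (0.3, 0.5, 0.75, 0.9):
            assert average_precision(preds, truths, thr) == pytest.approx(
                brute_force_ap(preds, truths, thr)
            )

    def test_invariant_under_monotone_confidence_rescale(self):
        truths = [DetectionRecord((0, 0, 4, 4)), DetectionRecord((10, 10, 14, 14))]
        preds = [
            DetectionRecord((0, 0, 4, 3), confidence=0.9),
            DetectionRecord((10, 10, 14, 14), confidence=0.4),
            DetectionRecord((1, 1, 5, 5), confidence=0.6),
        ]
        base = average_precision(preds, truths, 0.5)
        rescaled = [
            DetectionRecord(p.box, confidence=p.confidence**3) for p in preds
        ]
        assert average_precision(rescaled, truths, 0.5) == pytest.approx(base)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], [DetectionRecord((0, 0, 1, 1))], 1.5)


class TestMapRange:
    def test_exactly_ten_thresholds(self):
        assert len(MAP_THRESHOLDS) == 10
        assert MAP_THRESHOLDS[0] == 0.50 and MAP_THRESHOLDS[-1] == 0.95

    def test_perfect_predictions_all_ones(self):
        truths = [DetectionRecord((0, 0, 2, 2)), DetectionRecord((5, 5, 8, 8))]
        preds = [DetectionRecord(t.box, confidence=1.0) for t in truths]
        res = map_range(preds, truths)
        assert all(v == pytest.approx(1.0) for v in res.per_threshold_ap.values())
        assert res.map50_95 == pytest.approx(1.0)

    def test_map50_95_never_exceeds_map50(self):
        truths = [DetectionRecord((0, 0, 4, 4)), DetectionRecord((10, 10, 14, 14))]
        preds = [
            DetectionRecord((0, 0, 4, 3.2), confidence=0.9),
            DetectionRecord((10, 10, 14, 12.5), confidence=0.8),
        ]
        res = map_range(preds, truths)
        assert res.map50_95 <= res.map50 + 1e-12

    def test_iou_cutoff_against_per_threshold_brute_force(self):
        # boxes overlapping at IoU = 0.6: match only for thresholds <= 0.6
        truths = [DetectionRecord((0, 0, 10, 1))]
        preds = [DetectionRecord((2.5, 0, 12.5, 1), confidence=0.9)]
        iou = box_iou(preds[0].box, truths[0].box)
        assert iou == pytest.approx(0.6)
        res = map_range(preds, truths)
        for thr, ap in res.per_threshold_ap.items():
            expect = brute_force_ap(preds, truths, thr)
            assert ap == pytest.approx(expect)
            assert ap == (1.0 if thr <= 0.6 else 0.0)


class TestComplexity:
    def test_minimal_case(self):
        rep = conv_complexity(1, 1, 1, 1, 1)
        assert rep.flops == 4 and rep.params == 1

    def test_documented_case(self):
        rep = conv_complexity(10, 10, 3, 3, 8)
        assert rep.flops == 44_800 and rep.params == 216
        assert isinstance(rep.flops, int) and isinstance(rep.params, int)

    def test_flops_is_twice_counted_macs(self):
        H, W, C_in, K, C_out = 2, 3, 2, 3, 2
        macs = 0
        for _ in itertools.product(range(H), range(W), range(C_out)):
            macs += C_in * K * K  # kernel multiply-accumulates
            macs += 1             # bias add slot
        assert conv_complexity(H, W, C_in, K, C_out).flops == 2 * macs

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            conv_complexity(0, 10, 3, 3, 8)


class TestAgreement:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = agreement_analysis(x, x)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_noiseless_line_recovery(self):
        manual = np.linspace(0.5, 5.2, 30)
        machine = 0.9737 * manual - 0.0310
        rep = agreement_analysis(machine, manual)
        assert rep.slope == pytest.approx(0.9737, abs=1e-10)
        assert rep.intercept == pytest.approx(-0.0310, abs=1e-10)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_data_matches_normal_equation_oracle(self, rng):
        x = rng.uniform(0.5, 5.0, 50)
        y = 0.95 * x + 0.1 + rng.normal(0, 0.1, 50)
        rep = agreement_analysis(y, x)
        # independent solve of the normal equations
        A = np.column_stack([x, np.ones_like(x)])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        assert rep.slope == pytest.approx(coef[0], abs=1e-10)
        assert rep.intercept == pytest.approx(coef[1], abs=1e-10)

    def test_summary_statistics(self):
        machine = np.array([0.59, 2.50, 5.10])
        manual = np.array([0.51, 2.47, 5.20])
        rep = agreement_analysis(machine, manual)
        assert rep.machine_stats["min"] == 0.59 and rep.machine_stats["max"] == 5.10
        assert rep.manual_stats["median"] == 2.47

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            agreement_analysis([1.0, 2.0], [3.0, 3.0])
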