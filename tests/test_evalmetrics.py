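"""IoU, matching, precision/recall/F1 and average precision."""

import numpy as np
import pytest

from wormscope.detproc import Detection
from wormscope.evalmetrics import (
    average_precision,
    box_iou,
    f1_score,
    iou_sweep,
    mask_iou,
    match_detections,
    precision_recall_f1,
)
from wormscope.instances import InstanceMask


def _row_mask(start, width):
    """1-px-high run of `width` pixels beginning at column `start`."""
    return InstanceMask(np.ones((1, width), bool), x0=start, y0=0)


def _mask_det(mask, score, det_id=0):
    return Detection(bbox=mask.bbox, score=score, id=det_id, mask=mask)


class TestIoU:
    def test_overlap_211_of_364_pixels_gives_0_58(self):
        # two 1-D pixel runs with |A∩B| = 211 and |A∪B| = 364
        a = _row_mask(0, 288)
        b = _row_mask(77, 287)
        assert a.intersection_area(b) == 211
        assert a.area + b.area - 211 == 364
        assert mask_iou(a, b) == pytest.approx(211 / 364)
        assert round(mask_iou(a, b), 2) == 0.58

    def test_identical_masks_give_one(self):
        m = InstanceMask(np.tri(8, 8, dtype=bool))
        assert mask_iou(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        assert mask_iou(_row_mask(0, 10), _row_mask(20, 10)) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(30):
            a = InstanceMask(rng.random((12, 12)) > 0.5) if rng.random() > 0.1 else _row_mask(0, 5)
            b = InstanceMask(rng.random((12, 12)) > 0.5) if rng.random() > 0.1 else _row_mask(2, 5)
            iou = mask_iou(a, b)
            assert iou == mask_iou(b, a)
            assert 0.0 <= iou <= 1.0

    def test_box_iou_hand_arithmetic(self):
        assert box_iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert box_iou((0, 0, 10, 10), (10, 0, 20, 10)) == 0.0
        assert box_iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            box_iou((0, 0, 0, 10), (0, 0, 5, 5))


def brute_force_match(preds, gts, iou_min, mode="box"):
    """Reference matcher: explicit score-ordered pass, recomputing all IoUs."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, preds[i].id))
    used = set()
    tp = 0
    for i in order:
        candidates = []
        for j in range(len(gts)):
            if j in used:
                continue
            if mode == "mask":
                iou = mask_iou(preds[i].mask, gts[j])
            else:
                iou = box_iou(preds[i].bbox, gts[j].bbox)
            candidates.append((iou, j))
        if not candidates:
            continue
        best_iou, best_j = max(candidates)
        if best_iou >= iou_min:
            used.add(best_j)
            tp += 1
    return tp, len(preds) - tp, len(gts) - tp


class TestMatching:
    def test_exact_prediction_is_tp(self):
        gt = _row_mask(0, 30)
        m = match_detections([_mask_det(gt, 0.9)], [gt])
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.pairs[0][2] == 1.0

    def test_single_use_ground_truth(self):
        gt = _row_mask(0, 30)
        near = _row_mask(1, 30)
        m = match_detections([_mask_det(gt, 0.9, 0), _mask_det(near, 0.8, 1)], [gt])
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_conservation_and_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n_p, n_g = int(rng.integers(0, 7)), int(rng.integers(1, 7))
            preds = []
            for i in range(n_p):
                x0, y0 = rng.uniform(0, 40, 2)
                preds.append(
                    Detection(
                        bbox=(float(x0), float(y0), float(x0 + rng.uniform(4, 20)), float(y0 + rng.uniform(4, 20))),
                        score=float(rng.uniform(0, 1)),
                        id=i,
                    )
                )
            gts = []
            for _j in range(n_g):
                x0, y0 = int(rng.integers(0, 40)), int(rng.integers(0, 40))
                gts.append(
                    InstanceMask(np.ones((int(rng.integers(4, 20)), int(rng.integers(4, 20))), bool), x0, y0)
                )
            m = match_detections(preds, gts, iou_min=0.3, mode="box")
            assert m.tp + m.fn == len(gts)
            assert m.tp + m.fp == len(preds)
            assert all(iou >= 0.3 for _, _, iou in m.pairs)
            assert (m.tp, m.fp, m.fn) == brute_force_match(preds, gts, 0.3)

    def test_raising_iou_min_never_increases_tp(self, easy_plate):
        _, _, gts = easy_plate
        preds = [_mask_det(g.translate(2, 1), 0.9, i) for i, g in enumerate(gts)]
        tps = [match_detections(preds, gts, iou_min=t).tp for t in (0.3, 0.5, 0.7, 0.9)]
        assert tps == sorted(tps, reverse=True)


# printed (precision, recall, F1) triples of the detector's published
# per-threshold evaluation; F1 must be their harmonic mean at print precision
TABLE_ROWS = [
    (0.960, 0.956, 0.958),
    (0.907, 0.93, 0.918),
    (0.912, 0.934, 0.923),
    (0.913, 0.936, 0.924),
    (0.896, 0.917, 0.906),
    (0.864, 0.886, 0.875),
    (0.777, 0.796, 0.786),
    (0.499, 0.510, 0.504),
    (0.0081, 0.0083, 0.0082),
]


class TestMetrics:
    @pytest.mark.parametrize("precision, recall, f1", TABLE_ROWS)
    def test_f1_is_harmonic_mean_at_printed_precision(self, precision, recall, f1):
        decimals = len(str(f1).split(".")[1])
        assert round(f1_score(precision, recall), decimals) == f1

    def test_no_predictions_flags_precision(self):
        from wormscope.evalmetrics import MatchResult

        m = MatchResult(tp=0, fp=0, fn=5, pairs=[], iou_min=0.5)
        with pytest.warns(UserWarning, match="precision undefined"):
            metrics = precision_recall_f1(m)
        assert np.isnan(metrics.precision)
        assert metrics.recall == 0.0

    def test_avg_mask_iou_over_matched_pairs(self):
        gt = _row_mask(0, 100)
        pred = _mask_det(_row_mask(10, 100), 0.9)  # IoU 90/110
        m = match_detections([pred], [gt], iou_min=0.5)
        metrics = precision_recall_f1(m)
        assert metrics.avg_mask_iou == pytest.approx(90 / 110)


def numeric_envelope_ap(tp_flags, n_gt, grid=200_000):
    """Oracle: integrate max-precision-at-recall>=r on a dense recall grid."""
    tp_flags = np.asarray(tp_flags, dtype=float)
    cum_tp = np.cumsum(tp_flags)
    recalls = cum_tp / n_gt
    precisions = cum_tp / np.arange(1, len(tp_flags) + 1)
    rs = np.linspace(0, recalls.max() if len(recalls) else 0.0, grid, endpoint=False)
    ps = np.empty_like(rs)
    for k, r in enumerate(rs):
        ps[k] = precisions[recalls > r].max() if (recalls > r).any() else 0.0
    return float(ps.mean() * (recalls.max() if len(recalls) else 0.0))


def _ranked_fixture(tp_flags, n_gt):
    """Detections and disjoint gts realizing a given ranked TP/FP sequence."""
    gts = [_row_mask(0, 10).translate(0, 3 * j) for j in range(n_gt)]
    preds = []
    next_gt = 0
    for i, flag in enumerate(tp_flags):
        if flag and next_gt < n_gt:
            mask = gts[next_gt]
            next_gt += 1
        else:
            mask = _row_mask(1000 + 20 * i, 10)
        preds.append(Detection(bbox=mask.bbox, score=1.0 - i * 0.01, id=i, mask=mask))
    return preds, gts


class TestAveragePrecision:
    def test_perfect_detection_gives_ap_one(self):
        preds, gts = _ranked_fixture([1, 1, 1], 3)
        assert average_precision(preds, gts).ap == pytest.approx(1.0)

    def test_no_matches_gives_ap_zero(self):
        preds, gts = _ranked_fixture([0, 0], 2)
        assert average_precision(preds, gts).ap == 0.0

    def test_hand_ranking_matches_envelope_integration_oracle(self):
        flags = [1, 0, 1, 1, 0]
        preds, gts = _ranked_fixture(flags, 3)
        curve = average_precision(preds, gts)
        assert curve.ap == pytest.approx(numeric_envelope_ap(flags, 3), abs=1e-4)

    def test_ap_equals_recall_when_no_false_positives(self):
        preds, gts = _ranked_fixture([1, 1], 4)
        curve = average_precision(preds, gts)
        assert curve.ap == pytest.approx(0.5)

    def test_zero_ground_truths_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], [])

    def test_recall_non_decreasing_along_curve(self):
        preds, gts = _ranked_fixture([1, 0, 1, 0, 1, 1], 5)
        curve = average_precision(preds, gts)
        assert (np.diff(curve.recalls) >= 0).all()


class TestIoUSweep:
    def _fixture(self, easy_plate):
        _, _, gts = easy_plate
        preds = [_mask_det(g.translate(1, 1), 0.95 - 0.01 * i, i) for i, g in enumerate(gts)]
        return preds, gts

    def test_f1_non_increasing_with_threshold(self, easy_plate):
        preds, gts = self._fixture(easy_plate)
        table = iou_sweep(preds, gts, [0.2, 0.4, 0.6, 0.8])
        f1 = table["f1"].to_numpy()
        assert (np.diff(f1) <= 1e-12).all()

    def test_single_threshold_row_equals_individual_calls(self, easy_plate):
        preds, gts = self._fixture(easy_plate)
        table = iou_sweep(preds, gts, [0.5])
        m = match_detections(preds, gts, iou_min=0.5)
        metrics = precision_recall_f1(m)
        curve = average_precision(preds, gts, iou_min=0.5)
        row = table.iloc[0]
        assert row["precision"] == metrics.precision
        assert row["recall"] == metrics.recall
        assert row["f1"] == metrics.f1
        assert row["ap"] == curve.ap

    def test_out_of_range_threshold_rejected(self, easy_plate):
        preds, gts = self._fixture(easy_plate)
        with pytest.raises(ValueError):
            iou_sweep(preds, gts, [0.0])
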