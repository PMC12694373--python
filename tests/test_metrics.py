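"""Evaluation: IoU arithmetic, AP against independent oracles, mAP behaviour."""

import numpy as np
import pytest

from leafdet.metrics import (
    COCO_THRESHOLDS, Detection, GroundTruth, average_precision,
    box_iou_matrix, iou, map_eval, nms,
)


def D(img, cat, box, score):
    return Detection(image_id=img, category_id=cat, box=box, score=score)


def G(img, cat, box):
    return GroundTruth(image_id=img, category_id=cat, box=box)


# ---------------------------------------------------------------------------
# independent oracles (deliberately different algorithms from the package)
# ---------------------------------------------------------------------------

def brute_force_ap_all_cutoffs(dets, gts, thr, interpolation="allpoint"):
    """Enumerate every confidence cutoff, rebuild (P, R) from scratch, and
    integrate the envelope geometrically."""
    order = sorted(dets, key=lambda d: -d.score)
    # greedy matching identical in contract, re-derived independently
    flags = []
    used = set()
    for d in order:
        best, bj = 0.0, None
        for j, g in enumerate(gts):
            if j in used or g.image_id != d.image_id:
                continue
            v = iou(d.box, g.box)
            if v > best:
                best, bj = v, j
        if bj is not None and best >= thr:
            used.add(bj)
            flags.append(True)
        else:
            flags.append(False)
    points = []
    for cut in range(1, len(order) + 1):
        tp = sum(flags[:cut])
        points.append((tp / len(gts), tp / cut))
    if interpolation == "allpoint":
        ap, prev_r = 0.0, 0.0
        for r in sorted({r for r, _ in points}):
            best_p = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * best_p
            prev_r = r
        return ap
    # 101-point rule, written from the definition
    total = 0.0
    for rp in np.linspace(0, 1, 101):
        cands = [p for r, p in points if r >= rp - 1e-12]
        total += max(cands) if cands else 0.0
    return total / 101


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_hand_computed_overlap(self):
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(2 / 6)

    def test_degenerate_box_contributes_zero(self):
        assert iou((1, 1, 1, 3), (0, 0, 4, 4)) == 0.0

    def test_matrix_agrees_with_scalar(self, rng):
        a = np.sort(rng.uniform(0, 10, size=(6, 2, 2)), axis=2).reshape(6, 4)[:, [0, 2, 1, 3]]
        b = np.sort(rng.uniform(0, 10, size=(4, 2, 2)), axis=2).reshape(4, 4)[:, [0, 2, 1, 3]]
        m = box_iou_matrix(a, b)
        for i in range(6):
            for j in range(4):
                assert m[i, j] == pytest.approx(iou(a[i], b[j]), abs=1e-12)


class TestAveragePrecision:
    def test_perfect_detector_scores_one(self):
        gts = [G(0, 0, (0, 0, 10, 10)), G(1, 0, (5, 5, 20, 20))]
        dets = [D(0, 0, (0, 0, 10, 10), 0.9), D(1, 0, (5, 5, 20, 20), 0.8)]
        assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)
        assert average_precision(dets, gts, 0.5, "allpoint") == pytest.approx(1.0)

    def test_no_detections_scores_zero(self):
        assert average_precision([], [G(0, 0, (0, 0, 10, 10))], 0.5) == 0.0

    def test_fp_before_tp_two_point_curve(self):
        # one GT; [(FP, 0.9), (TP, 0.8)] -> PR points (0,0), (1, 0.5) -> 0.5
        gts = [G(0, 0, (0, 0, 10, 10))]
        dets = [D(0, 0, (50, 50, 60, 60), 0.9), D(0, 0, (0, 0, 10, 10), 0.8)]
        assert average_precision(dets, gts, 0.5, "allpoint") == pytest.approx(0.5)

    def test_no_ground_truths_raises(self):
        with pytest.raises(ValueError):
            average_precision([D(0, 0, (0, 0, 1, 1), 0.5)], [], 0.5)

    @pytest.mark.parametrize("interpolation", ["allpoint", "101point"])
    def test_matches_brute_force_all_cutoff_oracle(self, rng, interpolation):
        for trial in range(30):
            n_gt = int(rng.integers(1, 6))
            n_det = int(rng.integers(1, 20))
            gts = [G(int(rng.integers(0, 3)), 0,
                     tuple(np.sort(rng.uniform(0, 50, 4).reshape(2, 2), axis=0).ravel()))
                   for _ in range(n_gt)]
            dets = []
            for _ in range(n_det):
                if rng.random() < 0.5 and gts:
                    g = gts[int(rng.integers(0, n_gt))]
                    x0, y0, x1, y1 = g.box
                    jitter = rng.uniform(-3, 3, 4)
                    box = (x0 + jitter[0], y0 + jitter[1],
                           max(x0 + jitter[0] + 1, x1 + jitter[2]),
                           max(y0 + jitter[1] + 1, y1 + jitter[3]))
                    img = g.image_id
                else:
                    box = tuple(np.sort(rng.uniform(0, 50, 4).reshape(2, 2), axis=0).ravel())
                    img = int(rng.integers(0, 3))
                dets.append(D(img, 0, box, float(rng.random())))
            got = average_precision(dets, gts, 0.4, interpolation)
            ref = brute_force_ap_all_cutoffs(dets, gts, 0.4, interpolation)
            assert got == pytest.approx(ref, abs=1e-10)

    def test_greedy_matching_consumes_each_gt_once(self):
        """Two detections colliding on one GT: only the more confident one
        may count as TP."""
        gts = [G(0, 0, (0, 0, 10, 10))]
        dets = [D(0, 0, (0, 0, 10, 10), 0.9), D(0, 0, (1, 1, 10, 10), 0.8)]
        # precision after 2 dets = 1 TP / 2 -> all-point AP = 1.0 (recall hit at rank 1)
        assert average_precision(dets, gts, 0.5, "allpoint") == pytest.approx(1.0)
        # reversed confidences: lower-quality det claims it first
        dets_r = [D(0, 0, (1, 1, 10, 10), 0.9), D(0, 0, (0, 0, 10, 10), 0.8)]
        assert average_precision(dets_r, gts, 0.5, "allpoint") == pytest.approx(1.0)
        # but with a threshold the weaker first match can fail entirely
        assert average_precision(dets_r, gts, 0.9, "allpoint") == pytest.approx(0.5)


class TestMapEval:
    def _perfect(self):
        gts = [G(i, c, (10 * c, 0, 10 * c + 8, 8)) for i in range(3)
               for c in range(2)]
        dets = [D(g.image_id, g.category_id, g.box, 0.9) for g in gts]
        return dets, gts

    def test_perfect_detector_maps_are_one(self):
        dets, gts = self._perfect()
        res = map_eval(dets, gts)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)

    def test_strict_thresholds_degrade_before_loose_ones(self):
        # shift boxes by half their width: IoU = 1/3 -> fails even at 0.50;
        # use a smaller shift giving IoU ~ 0.6: passes 0.50, fails 0.75
        gts = [G(0, 0, (0, 0, 10, 10))]
        dets = [D(0, 0, (2.5, 0, 12.5, 10), 0.9)]   # IoU = 7.5/12.5 = 0.6
        res = map_eval(dets, gts, thresholds=(0.5, 0.75))
        assert res.per_class_ap[0.5][0] == pytest.approx(1.0)
        assert res.per_class_ap[0.75][0] == 0.0

    def test_map5095_not_above_map50(self, rng):
        gts = [G(i, 0, tuple(np.sort(rng.uniform(0, 40, 4).reshape(2, 2), axis=0).ravel()))
               for i in range(5)]
        dets = [D(g.image_id, 0, tuple(np.asarray(g.box) + rng.uniform(-2, 2, 4)), float(rng.random()))
                for g in gts]
        dets = [d for d in dets if d.box[0] < d.box[2] and d.box[1] < d.box[3]]
        res = map_eval(dets, gts)
        assert res.map50_95 <= res.map50 + 1e-9

    def test_invariant_to_detection_order(self, rng):
        dets, gts = self._perfect()
        extra = [D(0, 1, (50, 50, 60, 60), float(s)) for s in rng.random(5)]
        all_dets = dets + extra
        r1 = map_eval(all_dets, gts)
        perm = [all_dets[i] for i in rng.permutation(len(all_dets))]
        r2 = map_eval(perm, gts)
        assert r1.map50 == pytest.approx(r2.map50, abs=1e-12)
        assert r1.map50_95 == pytest.approx(r2.map50_95, abs=1e-12)

    def test_unknown_detection_class_warns(self):
        dets, gts = self._perfect()
        with pytest.warns(UserWarning):
            map_eval(dets + [D(0, 99, (0, 0, 1, 1), 0.5)], gts)

    def test_default_thresholds_are_the_coco_ladder(self):
        assert COCO_THRESHOLDS == tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))
        assert len(COCO_THRESHOLDS) == 10


class TestNMS:
    def test_suppresses_heavy_overlap_keeps_distinct(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40]])
        keep = nms(boxes, [0.9, 0.8, 0.7], iou_threshold=0.5)
        assert list(keep) == [0, 2]
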