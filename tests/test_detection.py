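import itertools
import math

import numpy as np
import pytest

from uwenhance import detection
from uwenhance.detection import Box, BraSpec


def brute_force_ap(dets, n_gt):
    """Independent rectangle-sum evaluation of all-point interpolated AP."""
    dets = sorted(dets, key=lambda d: -d[0])
    points = []
    tp = fp = 0
    for _, flag in dets:
        tp, fp = tp + int(flag), fp + int(not flag)
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        best_p = max(p for _, p in points[i:])
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap


class TestIou:
    def test_identical_boxes(self):
        b = Box(0, 0, 2, 3)
        assert detection.iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert detection.iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0

    def test_worked_overlap(self):
        assert detection.iou(Box(0, 0, 2, 2), Box(1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(1, 1, 1, 2)


class TestEclouLoss:
    def test_zero_at_coincidence(self):
        b = Box(2, 3, 5, 9)
        loss, terms = detection.eclou_loss(b, b)
        assert loss == 0.0 and terms.iou == 1.0 and terms.v == 0.0

    def test_worked_example(self):
        loss, terms = detection.eclou_loss(Box(1, 1, 3, 3), Box(0, 0, 2, 2))
        assert terms.iou == pytest.approx(1 / 7)
        assert terms.v == 0.0 and terms.rho2_center == pytest.approx(2.0)
        assert terms.c2 == pytest.approx(18.0)
        assert loss == pytest.approx(1 - 1 / 7 + 2 / 18, abs=1e-6)  # ~0.968254

    def test_loss_decreases_on_centered_approach(self):
        gt = Box(0, 0, 2, 2)
        losses = [detection.eclou_loss(Box(t, t, t + 2, t + 2), gt)[0] for t in np.linspace(1.5, 0.0, 12)]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_geometry_over_random_box_grid(self, rng):
        for _ in range(1000):
            x1, y1, x2, y2 = rng.uniform(0, 10, 4)
            a = Box(min(x1, x2), min(y1, y2), min(x1, x2) + abs(x2 - x1) + 0.1, min(y1, y2) + abs(y2 - y1) + 0.1)
            u1, v1, u2, v2 = rng.uniform(0, 10, 4)
            b = Box(min(u1, u2), min(v1, v2), min(u1, u2) + abs(u2 - u1) + 0.1, min(v1, v2) + abs(v2 - v1) + 0.1)
            loss, t = detection.eclou_loss(a, b)
            assert loss >= 0.0
            assert 0.0 <= 1.0 - t.iou <= 1.0
            assert 0.0 <= t.rho2_center / t.c2 <= 1.0
            assert 0.0 <= t.rho2_w / t.c2_w <= 1.0 and 0.0 <= t.rho2_h / t.c2_h <= 1.0
            # reported terms reproduce the loss exactly
            recon = (1 - t.iou) + t.alpha * t.v + t.rho2_center / t.c2 + t.rho2_h / t.c2_h + t.rho2_w / t.c2_w
            assert loss == pytest.approx(recon, abs=1e-12)

    def test_translation_and_scale_invariance(self, rng):
        pred, gt = Box(1, 2, 4, 5), Box(2, 1, 5, 6)
        base = detection.eclou_loss(pred, gt)[0]
        for dx, dy in [(3.5, -2.0), (-1.0, 7.25)]:
            shifted = detection.eclou_loss(
                Box(pred.x_min + dx, pred.y_min + dy, pred.x_max + dx, pred.y_max + dy),
                Box(gt.x_min + dx, gt.y_min + dy, gt.x_max + dx, gt.y_max + dy),
            )[0]
            assert shifted == pytest.approx(base, abs=1e-12)
        for s in (0.25, 3.0):
            scaled = detection.eclou_loss(
                Box(*(s * np.array([pred.x_min, pred.y_min, pred.x_max, pred.y_max]))),
                Box(*(s * np.array([gt.x_min, gt.y_min, gt.x_max, gt.y_max]))),
            )[0]
            assert scaled == pytest.approx(base, abs=1e-12)


class TestPrecisionRecall:
    def test_worked_values(self):
        p, r, flag = detection.precision_recall(8, 2, 8)
        assert p == pytest.approx(0.8) and r == pytest.approx(0.5) and not flag

    def test_undefined_reported_with_flag(self):
        p, r, flag = detection.precision_recall(0, 0, 0)
        assert p == 0.0 and r == 0.0 and flag

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            detection.precision_recall(-1, 0, 0)


class TestAveragePrecision:
    def test_worked_example(self):
        dets = [(0.9, True), (0.8, False), (0.7, True)]
        assert detection.average_precision(dets, 2) == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-6)

    def test_perfect_detector(self):
        assert detection.average_precision([(0.9, True), (0.8, True)], 2) == 1.0

    def test_map_is_unweighted_mean(self):
        assert detection.mean_average_precision({"a": 1.0, "b": 0.5}) == pytest.approx(0.75)

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            detection.average_precision([(0.5, True)], 0)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 11))
            n_gt = int(rng.integers(1, 6))
            dets = [(float(rng.random()), bool(rng.random() < 0.5)) for _ in range(n)]
            assert detection.average_precision(dets, n_gt) == pytest.approx(
                brute_force_ap(dets, n_gt), abs=1e-10
            )


class TestMatchDetections:
    def test_single_gt_double_detection(self):
        gt = [Box(0, 0, 2, 2)]
        preds = [Box(0, 0, 2, 2), Box(0.1, 0.1, 2.1, 2.1)]
        flags = detection.match_detections(preds, [0.6, 0.9], ["u", "u"], gt, ["u"])
        assert flags == [False, True]  # the higher-scoring one wins the GT

    def test_strict_iou_threshold(self):
        gt = [Box(0, 0, 10, 1)]
        pred = [Box(0, 0, 4.9, 1)]  # IoU 0.49
        assert detection.match_detections(pred, [0.9], ["u"], gt, ["u"], iou_thresh=0.5) == [False]

    def test_matches_exhaustive_greedy_oracle(self, rng):
        def oracle(preds, scores, gts, thresh):
            flags = [False] * len(preds)
            order = sorted(range(len(preds)), key=lambda i: -scores[i])
            taken = set()
            for i in order:
                ious = [
                    (detection.iou(preds[i], g), j) for j, g in enumerate(gts) if j not in taken
                ]
                if not ious:
                    continue
                best = max(ious, key=lambda t: t[0])
                if best[0] >= thresh:
                    flags[i] = True
                    taken.add(best[1])
            return flags

        for _ in range(20):
            gts = [
                Box(x, y, x + rng.uniform(1, 3), y + rng.uniform(1, 3))
                for x, y in rng.uniform(0, 8, size=(4, 2))
            ]
            preds = [
                Box(x0 := b.x_min + rng.uniform(-1, 1), y0 := b.y_min + rng.uniform(-1, 1),
                    x0 + b.width + rng.uniform(-0.5, 0.5), y0 + b.height + rng.uniform(-0.5, 0.5))
                for b in gts for _ in range(2)
            ]
            scores = list(rng.random(len(preds)))
            got = detection.match_detections(preds, scores, ["u"] * len(preds), gts, ["u"] * len(gts))
            assert got == oracle(preds, scores, gts, 0.5)


class TestEvaluateDetections:
    def test_two_class_table(self):
        import pandas as pd

        gt = pd.DataFrame(
            [
                {"image": "a", "class": "urchin", "x_min": 0, "y_min": 0, "x_max": 2, "y_max": 2},
                {"image": "a", "class": "star", "x_min": 5, "y_min": 5, "x_max": 7, "y_max": 7},
            ]
        )
        pred = pd.DataFrame(
            [
                {"image": "a", "class": "urchin", "x_min": 0, "y_min": 0, "x_max": 2, "y_max": 2, "score": 0.9},
                {"image": "a", "class": "star", "x_min": 0, "y_min": 0, "x_max": 1, "y_max": 1, "score": 0.8},
            ]
        )
        table = detection.evaluate_detections(pred, gt)
        by_class = dict(zip(table["class"], table["ap"]))
        assert by_class["urchin"] == 1.0 and by_class["star"] == 0.0
        assert by_class["mAP"] == pytest.approx(0.5)


def dense_attention_oracle(spec):
    """Loop-based full attention over every token pair, plus LCE."""
    h, w, c = spec.x.shape
    tokens = spec.x.reshape(-1, c)
    q, k, v = tokens @ spec.wq, tokens @ spec.wk, tokens @ spec.wv
    out = np.zeros_like(q)
    for i in range(q.shape[0]):
        logits = np.array([q[i] @ k[j] / math.sqrt(c) for j in range(k.shape[0])])
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        out[i] = sum(weights[j] * v[j] for j in range(v.shape[0]))
    vmap = v.reshape(h, w, c)
    lce = np.zeros_like(vmap)
    for y in range(h):
        for x in range(w):
            for dy in range(-2, 3):
                for dx in range(-2, 3):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        lce[y, x] += vmap[yy, xx] * spec.lce_kernel[dy + 2, dx + 2]
    return out.reshape(h, w, c) + lce


def make_spec(rng, s, k, h=8, w=8, c=4):
    return BraSpec(
        x=rng.standard_normal((h, w, c)),
        regions=s,
        top_k=k,
        wq=rng.standard_normal((c, c)) * 0.5,
        wk=rng.standard_normal((c, c)) * 0.5,
        wv=rng.standard_normal((c, c)) * 0.5,
        lce_kernel=rng.standard_normal((5, 5, c)) * 0.1,
    )


class TestBraForward:
    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_full_routing_equals_dense_attention(self, rng, s):
        spec = make_spec(rng, s, s * s)
        assert np.abs(detection.bra_forward(spec) - dense_attention_oracle(spec)).max() < 1e-8

    def test_single_region_single_route(self, rng):
        spec = make_spec(rng, 1, 1)
        assert np.abs(detection.bra_forward(spec) - dense_attention_oracle(spec)).max() < 1e-8

    def test_softmax_rows_normalized(self, rng):
        from uwenhance.detection import _softmax

        rows = _softmax(rng.standard_normal((16, 16)), axis=1)
        assert np.abs(rows.sum(axis=1) - 1.0).max() < 1e-10

    def test_sparse_routing_attends_to_k_regions_only(self, rng):
        # with k=1 each query region sees a quarter of the tokens of the dense case
        spec = make_spec(rng, 2, 1)
        sparse = detection.bra_forward(spec)
        dense = dense_attention_oracle(spec)
        assert np.abs(sparse - dense).max() > 1e-6  # genuinely different computation

    @pytest.mark.parametrize(
        "kwargs",
        [dict(s=3, k=1), dict(s=2, k=5)],
        ids=["regions-dont-divide", "k-out-of-range"],
    )
    def test_invalid_spec_rejected(self, rng, kwargs):
        with pytest.raises(ValueError):
            make_spec(rng, kwargs["s"], kwargs["k"])
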