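"""Loss and metric arithmetic, anchored to exact small-case values, plus the
Dice–Jaccard identity and greedy-vs-exhaustive matching oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from nucleiseg.metrics import (ConfusionCounts, MetricReport, dice_coefficient,
                               figure_of_merit, figure_of_merit_pr,
                               greedy_match, hybrid_loss, jaccard_iou,
                               match_objects, pairwise_iou, pixel_accuracy,
                               precision_recall_f1)

masks = hnp.arrays(np.uint8, (6, 7), elements=st.integers(0, 1))


class TestHybridLoss:
    def test_perfect_prediction_vanishes(self):
        t = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.clip(t, 1e-7, 1 - 1e-7)
        assert hybrid_loss(p, t) < 1e-5

    def test_alpha_endpoints_are_pure_terms(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, (4, 4))
        t = (rng.random((4, 4)) > 0.5).astype(float)
        bce = hybrid_loss(p, t, alpha=1.0)
        dice = hybrid_loss(p, t, alpha=0.0)
        assert np.isclose(hybrid_loss(p, t, alpha=0.5), 0.5 * bce + 0.5 * dice)

    def test_uniform_half_probability_bce_is_ln2(self):
        t = np.zeros((2, 8))
        t[:, :4] = 1.0  # half-foreground target
        p = np.full_like(t, 0.5)
        assert np.isclose(hybrid_loss(p, t, alpha=1.0), np.log(2.0))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            hybrid_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_loss_decreases_approaching_target(self):
        t = (np.random.default_rng(1).random((8, 8)) > 0.5).astype(float)
        losses = [hybrid_loss(np.clip(t, eps, 1 - eps), t)
                  for eps in (0.4, 0.2, 0.05, 0.01, 1e-4)]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-3

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, (3, 5))
        t = (rng.random((3, 5)) > 0.5).astype(float)
        w = np.array([1.0, 2.0, 0.5])
        loss, grad = hybrid_loss(p, t, sample_weight=w, return_grad=True)
        eps = 1e-7
        for idx in [(0, 0), (1, 3), (2, 4)]:
            pp = p.copy()
            pp[idx] += eps
            pm = p.copy()
            pm[idx] -= eps
            num = (hybrid_loss(pp, t, sample_weight=w)
                   - hybrid_loss(pm, t, sample_weight=w)) / (2 * eps)
            assert np.isclose(num, grad[idx], rtol=1e-5)


class TestPixelMetrics:
    def test_dice_exact_small_case(self):
        # |P| = |G| = 200, |P∩G| = 190 -> 0.95
        p = np.zeros((20, 20), dtype=np.uint8)
        g = np.zeros((20, 20), dtype=np.uint8)
        p.flat[:200] = 1
        g.flat[10:210] = 1
        assert dice_coefficient(p, g) == 0.95
        # IoU of the same pair: 190/210
        assert np.isclose(jaccard_iou(p, g), 190 / 210)
        assert round(jaccard_iou(p, g), 3) == 0.905

    def test_identical_and_disjoint_masks(self):
        m = (np.random.default_rng(0).random((9, 9)) > 0.6).astype(np.uint8)
        assert dice_coefficient(m, m) == 1.0
        assert jaccard_iou(m, m) == 1.0
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_empty_vs_empty_convention(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert dice_coefficient(z, z) == 1.0
        assert jaccard_iou(z, z) == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(p=masks, g=masks)
    def test_dice_jaccard_identity_and_symmetry(self, p, g):
        dsc = dice_coefficient(p, g)
        iou = jaccard_iou(p, g)
        assert np.isclose(iou * (2.0 - dsc), dsc, rtol=1e-12, atol=1e-12)
        assert dice_coefficient(g, p) == dsc
        assert 0.0 <= dsc <= 1.0 and 0.0 <= iou <= 1.0

    def test_intersection_monotonicity(self):
        # fixed |P|=|G|=50, growing overlap never decreases DSC/IoU/FoM
        prev = (-1.0, -1.0, -1.0)
        for inter in range(0, 51, 10):
            p = np.zeros(200, dtype=np.uint8)
            g = np.zeros(200, dtype=np.uint8)
            p[:50] = 1
            g[50 - inter:100 - inter] = 1
            c = ConfusionCounts.from_masks(p.reshape(10, 20), g.reshape(10, 20))
            cur = (dice_coefficient(p.reshape(10, 20), g.reshape(10, 20)),
                   jaccard_iou(p.reshape(10, 20), g.reshape(10, 20)),
                   figure_of_merit(c))
            assert all(a >= b for a, b in zip(cur, prev))
            prev = cur

    def test_pixel_accuracy_cases(self):
        assert pixel_accuracy(ConfusionCounts(10, 5, 0, 0)) == 1.0
        assert pixel_accuracy(ConfusionCounts(0, 0, 3, 2)) == 0.0
        assert pixel_accuracy(ConfusionCounts(50, 40, 5, 5)) == 0.90
        with pytest.raises(ValueError):
            pixel_accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_figure_of_merit_pixel_counts(self):
        # counts realizing precision 0.92 / recall 0.94
        c = ConfusionCounts(tp=1081, tn=0, fp=94, fn=69)
        assert np.isclose(figure_of_merit(c), 1081 / 1244)
        assert round(figure_of_merit(c), 3) == 0.869
        assert figure_of_merit(ConfusionCounts(7, 0, 0, 0)) == 1.0
        # counts realizing precision 0.85 / recall 0.88
        c2 = ConfusionCounts(tp=748, tn=0, fp=132, fn=102)
        assert round(figure_of_merit(c2), 3) == 0.762

    def test_figure_of_merit_from_precision_recall(self):
        assert round(figure_of_merit_pr(0.92, 0.94), 3) == 0.869
        assert round(figure_of_merit_pr(0.85, 0.88), 3) == 0.762

    def test_precision_recall_f1(self):
        c = ConfusionCounts(tp=1081, tn=0, fp=94, fn=69)
        prec, rec, f1 = precision_recall_f1(c)
        assert round(prec, 2) == 0.92 and round(rec, 2) == 0.94
        # harmonic mean of 0.92 and 0.93 -> 0.925
        f1_ref = 2 * 0.92 * 0.93 / (0.92 + 0.93)
        assert round(f1_ref, 3) == 0.925
        # degenerate: no positives anywhere
        assert precision_recall_f1(ConfusionCounts(0, 10, 0, 0)) == (0, 0, 0)
        # fixed point: precision == recall == r implies F1 == r
        c3 = ConfusionCounts(tp=30, tn=0, fp=10, fn=10)
        p3, r3, f3 = precision_recall_f1(c3)
        assert p3 == r3 == f3


def _square(y, x, size, shape=(20, 20)):
    m = np.zeros(shape, dtype=np.uint8)
    m[y:y + size, x:x + size] = 1
    return m


def _optimal_detections(iou, thr):
    """Brute-force maximum number of one-to-one matches above threshold."""
    n_pred, n_gt = iou.shape
    best = 0
    for k in range(min(n_pred, n_gt), 0, -1):
        for preds in itertools.permutations(range(n_pred), k):
            for gts in itertools.combinations(range(n_gt), k):
                if all(iou[p, g] > thr for p, g in zip(preds, gts)):
                    return k
    return best


class TestObjectMatching:
    def test_single_pair_threshold_is_strict(self):
        g = _square(5, 5, 10)
        p_hi = _square(5, 5, 10)
        p_hi[5:15, 5:8] = 0  # IoU = 70/100 = 0.7
        _, rate = match_objects([p_hi], [g], 0.5)
        assert rate == 1.0
        p_lo = _square(5, 5, 10)
        p_lo[5:15, 5:11] = 0  # IoU = 40/100 = 0.4
        _, rate = match_objects([p_lo], [g], 0.5)
        assert rate == 0.0
        # exactly at threshold does not count (strict inequality)
        p_eq = _square(5, 5, 10)
        p_eq[5:15, 5:10] = 0  # IoU = 0.5
        _, rate = match_objects([p_eq], [g], 0.5)
        assert rate == 0.0

    def test_one_prediction_cannot_detect_two_objects(self):
        # greedy one-to-one on an IoU matrix with one prediction against two
        # ground-truth objects at 0.7/0.6: only the stronger pair matches
        iou = np.array([[0.7, 0.6]])
        matches = greedy_match(iou, 0.5)
        assert matches == [(0, 0)]

    def test_greedy_tie_breaks_on_lower_gt_index(self):
        iou = np.array([[0.8, 0.8]])
        assert greedy_match(iou, 0.5) == [(0, 0)]

    def test_overlapping_instances_rejected(self):
        a = _square(0, 0, 5)
        b = _square(2, 2, 5)
        with pytest.raises(ValueError, match="overlap"):
            match_objects([a, b], [a])

    def test_greedy_equals_exhaustive_up_to_four_objects(self):
        # disjoint instance sets with jittered predictions, threshold 0.5:
        # greedy detection count must equal the brute-force optimum
        rng = np.random.default_rng(7)
        for trial in range(40):
            n_gt = int(rng.integers(1, 5))
            gts, cover = [], np.zeros((30, 30), dtype=np.uint8)
            for _ in range(n_gt):
                y, x = rng.integers(0, 24, size=2)
                m = _square(y, x, int(rng.integers(3, 7)), shape=(30, 30))
                m[cover > 0] = 0
                if m.any():
                    gts.append(m)
                    cover |= m
            preds, pcover = [], np.zeros_like(cover)
            for g in gts:
                if rng.random() < 0.2:
                    continue  # missed detection
                dy, dx = rng.integers(-3, 4, size=2)
                m = np.roll(np.roll(g, dy, axis=0), dx, axis=1)
                m[pcover > 0] = 0
                if m.any():
                    preds.append(m)
                    pcover |= m
            iou = pairwise_iou(preds, gts)
            assert len(greedy_match(iou, 0.5)) == _optimal_detections(iou, 0.5)

    def test_detection_rate_on_rendered_instances(self):
        gts = [_square(1, 1, 6), _square(10, 10, 6)]
        preds = [_square(1, 1, 6), _square(10, 13, 6)]  # second shifted: IoU=0.2
        matches, rate = match_objects(preds, gts, 0.5)
        assert matches == [(0, 0)]
        assert rate == 0.5


def test_metric_report_aggregate_and_identity():
    rng = np.random.default_rng(0)
    report = MetricReport()
    for i in range(3):
        p = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        g = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        row = report.add_image(f"img{i}", p, g)
        assert np.isclose(row["iou"] * (2 - row["dsc"]), row["dsc"])
        assert np.isclose(row["f1"],
                          2 * row["precision"] * row["recall"]
                          / (row["precision"] + row["recall"]))
    agg = report.aggregate()
    assert agg["n_images"] == 3
    assert all(0 <= agg[c] <= 1 for c in ("dsc", "iou", "accuracy"))
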