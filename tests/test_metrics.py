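"""Metric and loss oracles: brute-force per-pixel loops and scalar arithmetic."""

import itertools

import numpy as np
import pytest

from appleseg import (ConfusionCounts, EvaluatedSample, LossConfig,
                      confusion, csre, f_score, focal_tversky_loss,
                      per_class_report, tversky_index)
from appleseg.core_data import DefectAnnotation
from appleseg.metrics import focal_tversky_loss_grad


def loop_confusion(pred, gt):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = pred[i, j], gt[i, j]
            tp += p and g
            fp += p and not g
            tn += (not p) and (not g)
            fn += (not p) and g
    return tp, fp, tn, fn


def loop_tversky(prob, gt, alpha, eps):
    num = den_fn = den_fp = 0.0
    for p, g in zip(prob.ravel(), gt.ravel()):
        num += p * g
        den_fn += (1 - p) * g
        den_fp += p * (1 - g)
    return (num + eps) / (num + alpha * den_fn + (1 - alpha) * den_fp + eps)


class TestConfusion:
    def test_matches_per_pixel_loop_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = rng.integers(0, 2, (16, 16))
            gt = rng.integers(0, 2, (16, 16))
            c = confusion(pred, gt)
            assert (c.tp, c.fp, c.tn, c.fn) == loop_confusion(pred, gt)
            assert c.n == 256

    def test_degenerate_pairs(self):
        gt = np.array([[1, 0], [0, 1]])
        c = confusion(gt, gt)
        assert c.fp == 0 and c.fn == 0
        c = confusion(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0

    def test_rejects_shape_mismatch_and_nonbinary(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestScalarMetrics:
    def test_csre_worked_example(self):
        c = ConfusionCounts(tp=8, fn=2, fp=5, tn=85)
        assert csre(c) == pytest.approx((0.2 + 5 / 90) / 2)

    def test_csre_extremes(self):
        assert csre(ConfusionCounts(tp=5, tn=5)) == 0.0
        assert csre(ConfusionCounts(fp=5, fn=5)) == 1.0

    def test_csre_is_one_minus_balanced_accuracy_exhaustive(self):
        # exhaustive grid of counts with N <= 20
        for tp, fn, fp, tn in itertools.product(range(6), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue
            c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
            recall = tp / (tp + fn)
            specificity = tn / (tn + fp)
            assert csre(c) == pytest.approx(1 - (recall + specificity) / 2)

    def test_f_score_worked_example(self):
        f = f_score(ConfusionCounts(tp=8, fp=5, fn=2))
        assert f.precision == pytest.approx(8 / 13)
        assert f.recall == pytest.approx(0.8)
        assert f.f == pytest.approx(16 / 23)

    def test_f_score_two_forms_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn = rng.integers(1, 20, 3)
            f = f_score(ConfusionCounts(tp=tp, fp=fp, fn=fn))
            harmonic = 2 * f.precision * f.recall / (f.precision + f.recall)
            assert f.f == pytest.approx(harmonic)

    def test_zero_overlap_convention(self):
        f = f_score(ConfusionCounts(tp=0, fp=3, fn=4))
        assert f == (0.0, 0.0, 0.0)


class TestFocalTverskyLoss:
    CFG = LossConfig(alpha=0.5, gamma=1.0, epsilon=1e-12)

    def test_scalar_fixture(self):
        p = np.array([0.8, 0.2, 0.0, 0.0])
        g = np.array([1, 0, 0, 0])
        assert tversky_index(p, g, self.CFG) == pytest.approx(0.8, abs=1e-9)
        assert focal_tversky_loss(p, g, self.CFG) == pytest.approx(0.2, abs=1e-9)
        cfg075 = LossConfig(alpha=0.5, gamma=0.75, epsilon=1e-12)
        assert focal_tversky_loss(p, g, cfg075) == pytest.approx(
            0.2 ** (4 / 3), abs=1e-9)

    def test_perfect_prediction_zero_loss(self):
        g = np.array([[1, 0], [0, 1]], dtype=float)
        assert focal_tversky_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_empty_class_convention(self):
        z = np.zeros((4, 4))
        assert tversky_index(z, z) == pytest.approx(1.0)

    def test_vectorized_equals_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            prob = rng.random((8, 8))
            gt = rng.integers(0, 2, (8, 8))
            for alpha in (0.1, 0.5, 0.9):
                cfg = LossConfig(alpha=alpha, epsilon=1e-6)
                assert tversky_index(prob, gt, cfg) == pytest.approx(
                    loop_tversky(prob, gt, alpha, 1e-6), abs=1e-10)

    def test_monotonicity(self):
        """Raising p on a positive pixel never increases the loss; raising
        p on a negative pixel never decreases it."""
        rng = np.random.default_rng(3)
        cfg = LossConfig()
        for _ in range(100):
            prob = rng.random((6, 6)) * 0.9
            gt = rng.integers(0, 2, (6, 6))
            if gt.sum() == 0 or gt.sum() == gt.size:
                continue
            base = focal_tversky_loss(prob, gt, cfg)
            pos = np.argwhere(gt == 1)[0]
            neg = np.argwhere(gt == 0)[0]
            up = prob.copy(); up[tuple(pos)] += 0.05
            assert focal_tversky_loss(up, gt, cfg) <= base + 1e-12
            up = prob.copy(); up[tuple(neg)] += 0.05
            assert focal_tversky_loss(up, gt, cfg) >= base - 1e-12

    def test_alpha_orientation(self):
        """The Tversky denominator weights the false-negative mass by alpha
        and the false-positive mass by 1-alpha, so TI strictly decreases in
        alpha whenever FN mass exceeds FP mass: a larger alpha penalises
        missed defect pixels more (recall-oriented loss)."""
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(100):
            prob = rng.random((6, 6)) * 0.8
            gt = rng.integers(0, 2, (6, 6))
            fn_mass = ((1 - prob) * gt).sum()
            fp_mass = (prob * (1 - gt)).sum()
            if fn_mass <= fp_mass:
                continue
            checked += 1
            tis = [tversky_index(prob, gt, LossConfig(alpha=a))
                   for a in (0.1, 0.5, 0.9)]
            assert tis[0] > tis[1] > tis[2]
        assert checked >= 20

    def test_alpha_raises_fn_gradient_weight(self):
        """With larger alpha the loss gradient pushes harder on ground-truth
        positive pixels relative to negatives, on every random fixture."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            prob = rng.random((6, 6)) * 0.8 + 0.1
            gt = rng.integers(0, 2, (6, 6))
            if gt.sum() in (0, gt.size):
                continue
            ratios = []
            for a in (0.2, 0.8):
                _, grad = focal_tversky_loss_grad(prob, gt, LossConfig(alpha=a))
                push_pos = -grad[gt == 1].sum()   # descent raises p here
                push_neg = grad[gt == 0].sum()    # descent lowers p here
                ratios.append(push_pos / max(push_neg, 1e-12))
            assert ratios[1] > ratios[0]

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        prob = rng.random((5, 5)) * 0.8 + 0.1
        gt = rng.integers(0, 2, (5, 5))
        cfg = LossConfig(alpha=0.3, gamma=0.75)
        _, grad = focal_tversky_loss_grad(prob, gt, cfg)
        eps = 1e-7
        for idx in [(0, 0), (2, 3), (4, 4)]:
            up = prob.copy(); up[idx] += eps
            dn = prob.copy(); dn[idx] -= eps
            num = (focal_tversky_loss(up, gt, cfg)
                   - focal_tversky_loss(dn, gt, cfg)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestPerClassReport:
    @staticmethod
    def _sample(sid, gt_regions, pred):
        gt = np.zeros((8, 8), dtype=np.uint8)
        defects = []
        for sub, region in gt_regions:
            gt |= region.astype(np.uint8)
            defects.append(DefectAnnotation(defect_mask=region, sub_class=sub))
        return EvaluatedSample(sample_id=sid, pred_mask=pred, gt_mask=gt,
                               defects=defects)

    def test_perfect_predictions_give_zero_error(self):
        r1 = np.zeros((8, 8), dtype=bool); r1[1:3, 1:3] = True
        r2 = np.zeros((8, 8), dtype=bool); r2[5:7, 5:7] = True
        s1 = self._sample("a", [("bruise", r1)], r1.astype(np.uint8))
        s2 = self._sample("b", [("rot", r2)], r2.astype(np.uint8))
        with pytest.warns(UserWarning):
            df = per_class_report([s1, s2], "sub")
        assert set(df["class"]) == {"bruise", "rot"}
        assert (df["csre"] == 0).all() and (df["f_score"] == 1).all()

    def test_other_class_pixels_are_ignored(self):
        """A two-class image: scoring class A must not penalise detections
        on class B's pixels (hand-computed tallies)."""
        ra = np.zeros((8, 8), dtype=bool); ra[0:2, 0:2] = True   # 4 px
        rb = np.zeros((8, 8), dtype=bool); rb[6:8, 6:8] = True   # 4 px
        pred = (ra | rb).astype(np.uint8)  # detects both regions
        s = self._sample("a", [("bruise", ra), ("rot", rb)], pred)
        with pytest.warns(UserWarning):
            df = per_class_report([s], "sub").set_index("class")
        # for bruise: rb pixels are ignore-labelled -> no false positives
        assert df.loc["bruise", "f_score"] == 1.0
        assert df.loc["bruise", "csre"] == 0.0
        assert df.loc["rot", "f_score"] == 1.0

    def test_macro_level_single_class_fixture(self):
        r = np.zeros((8, 8), dtype=bool); r[2:5, 2:5] = True
        pred = np.zeros((8, 8), dtype=np.uint8); pred[2:5, 2:6] = 1  # 3 FPs
        s = self._sample("a", [("russet", r)], pred)
        with pytest.warns(UserWarning):
            df = per_class_report([s], "macro").set_index("class")
        # russet -> slight_defect; tallies: TP=9, FP=3, FN=0, TN=52
        assert df.loc["slight_defect", "recall"] == 1.0
        assert df.loc["slight_defect", "precision"] == pytest.approx(9 / 12)
        assert df.loc["slight_defect", "csre"] == pytest.approx(0.5 * 3 / 55)
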