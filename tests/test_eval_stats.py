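"""Image-level detection outcomes, proportion metrics, ROC/AUC, DeLong,
and the two-proportion z-test, each against independent recomputation."""

import math

import numpy as np
import pytest

from fundusfusion.evalstats import (
    auc_ci_delong,
    classify_detection_image,
    dataset_profile,
    delong_test,
    detection_metrics,
    map_messidor_grade,
    roc_auc,
    two_proportion_z_test,
    youden_threshold,
    DetectionOutcome,
)
from fundusfusion.geometry import Box, iou
from .conftest import random_box


class TestClassifyDetectionImage:
    def test_both_empty_is_tn(self):
        assert classify_detection_image([], []).category == "TN"

    def test_overlapping_prediction_is_tp(self):
        out = classify_detection_image([Box(5, 0, 15, 10)], [Box(0, 0, 10, 10)])
        assert out.category == "TP"  # IoU 1/3 > 0.15

    def test_distant_prediction_is_fn(self):
        out = classify_detection_image([Box(50, 50, 60, 60)], [Box(0, 0, 10, 10)])
        assert out.category == "FN"

    def test_prediction_without_gt_is_fp(self):
        assert classify_detection_image([Box(0, 0, 5, 5)], []).category == "FP"

    def test_gt_without_prediction_is_fn(self):
        assert classify_detection_image([], [Box(0, 0, 5, 5)]).category == "FN"

    def test_iou_exactly_threshold_is_fn(self):
        # IoU exactly 0.15 does not count as a hit
        pred, gt = Box(0, 0, 10, 3), Box(0, 0, 10, 20)
        assert iou(pred, gt) == pytest.approx(0.15)
        assert classify_detection_image([pred], [gt]).category == "FN"

    def test_exactly_one_category_on_random_instances(self, rng):
        """The four definitions partition the outcome space."""
        for _ in range(200):
            pred = [random_box(rng) for _ in range(rng.integers(0, 3))]
            gt = [random_box(rng) for _ in range(rng.integers(0, 3))]
            cat = classify_detection_image(pred, gt).category
            hit = any(iou(p, g) > 0.15 for p in pred for g in gt)
            expected = (
                "TP" if gt and hit
                else "FN" if gt
                else "FP" if pred
                else "TN"
            )
            assert cat == expected


class TestDetectionMetrics:
    @staticmethod
    def outcomes(tp, fp, tn, fn):
        out = []
        for cat, n in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
            out.extend(DetectionOutcome(f"{cat}{i}", cat) for i in range(n))
        return out

    def test_testing_set_sized_confusion_table(self):
        rep = detection_metrics(self.outcomes(tp=290, fn=75, tn=600, fp=84))
        assert rep.sensitivity.value == pytest.approx(290 / 365, abs=1e-12)
        assert rep.specificity.value == pytest.approx(600 / 684, abs=1e-12)
        assert rep.accuracy.value == pytest.approx(890 / 1049, abs=1e-12)
        assert rep.sensitivity.ci_low < rep.sensitivity.value < rep.sensitivity.ci_high

    def test_all_tp_leaves_specificity_absent(self):
        rep = detection_metrics(self.outcomes(tp=5, fp=0, tn=0, fn=0))
        assert rep.sensitivity.value == 1.0
        assert rep.specificity is None

    def test_permutation_invariant(self, rng):
        outs = self.outcomes(3, 4, 5, 6)
        shuffled = [outs[i] for i in rng.permutation(len(outs))]
        a, b = detection_metrics(outs), detection_metrics(shuffled)
        assert a.sensitivity.value == b.sensitivity.value
        assert a.n_per_category == b.n_per_category


def brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_matches_concordance_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_curve_endpoints_and_monotone(self, rng):
        curve, _ = roc_auc(rng.random(40), rng.integers(0, 2, 40) | (np.arange(40) == 0))
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_youden_threshold_separates_perfect_scores(self):
        t = youden_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert 0.2 < t <= 0.8


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:5], y[5:10] = 1, 0
        auc_a, auc_b, z, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_auc_matches_roc_module(self, rng):
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:6], y[6:12] = 1, 0
        auc, ci = auc_ci_delong(s, y)
        _, auc_ref = roc_auc(s, y)
        assert auc == pytest.approx(auc_ref, abs=1e-12)
        assert ci.ci_low <= auc <= ci.ci_high

    def test_perfect_separation_ci_clipped_to_one(self):
        scores = np.r_[np.linspace(0.6, 0.9, 10), np.linspace(0.1, 0.4, 10)]
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        auc, ci = auc_ci_delong(scores, labels)
        assert auc == 1.0
        assert ci.ci_high == 1.0

    def test_small_class_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test(rng.random(6), rng.random(6), [1, 1, 0, 0, 0, 0])


class TestTwoProportionZ:
    def test_identical_proportions(self):
        z, p = two_proportion_z_test(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0

    def test_matches_pooled_formula(self):
        x1, n1, x2, n2 = 290, 365, 266, 365
        z, p = two_proportion_z_test(x1, n1, x2, n2)
        p1, p2 = x1 / n1, x2 / n2
        pool = (x1 + x2) / (n1 + n2)
        se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        z_ref = (p1 - p2) / se
        assert z == pytest.approx(z_ref, abs=1e-10)
        from scipy.stats import norm

        assert p == pytest.approx(2 * norm.sf(abs(z_ref)), abs=1e-10)

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(UserWarning):
            z, p = two_proportion_z_test(0, 10, 0, 20)
        assert p == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z_test(5, 4, 1, 10)


class TestDatasetProfile:
    def test_single_dme_split(self):
        table = dataset_profile({"val": [1]})
        row = table[(table["split"] == "val") & (table["class"] == "DME")].iloc[0]
        assert row["percent"] == 100.00

    def test_percentages_sum_to_hundred(self, rng):
        labels = {"train": rng.integers(0, 2, 333).tolist(),
                  "test": rng.integers(0, 2, 77).tolist()}
        table = dataset_profile(labels)
        for split in labels:
            sub = table[(table["split"] == split) & (table["class"] != "Total")]
            assert sub["percent"].sum() == pytest.approx(100.0, abs=0.01)


class TestMessidorGradeMapping:
    @pytest.mark.parametrize("grade,label", [(0, 0), (1, 0), (2, 1)])
    def test_mapping(self, grade, label):
        assert map_messidor_grade(grade) == label

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            map_messidor_grade(3)
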