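"""Image-level detection evaluation, ROC/AUC, DeLong, and proportion tests.

Detection is scored per image, not per box: an image with ground-truth
lesions counts as a true positive as soon as any predicted box overlaps any
ground-truth box with IoU strictly above the threshold (default 0.15); an
image without lesions and without predictions is a true negative; predictions
on a lesion-free image make it a false positive; everything else is a false
negative.  Sensitivity, specificity and accuracy follow with Wald (or Wilson)
95% intervals, AUC by midrank concordance with a DeLong interval, model
comparison by the DeLong test for correlated AUCs and an unpaired
two-proportion z-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .geometry import Box, iou

__all__ = [
    "DetectionOutcome",
    "RatioWithCI",
    "MetricsReport",
    "RocCurve",
    "classify_detection_image",
    "detection_metrics",
    "roc_auc",
    "auc_ci_delong",
    "delong_test",
    "two_proportion_z_test",
    "dataset_profile",
    "map_messidor_grade",
    "youden_threshold",
]

DETECTION_IOU_THRESHOLD = 0.15
ALPHA = 0.05  # statistical significance threshold


@dataclass(frozen=True)
class DetectionOutcome:
    image_id: str
    category: str  # TP | FP | TN | FN

    def __post_init__(self) -> None:
        if self.category not in ("TP", "FP", "TN", "FN"):
            raise ValueError(f"unknown outcome category {self.category!r}")


@dataclass(frozen=True)
class RatioWithCI:
    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class MetricsReport:
    sensitivity: Optional[RatioWithCI]
    specificity: Optional[RatioWithCI]
    accuracy: Optional[RatioWithCI]
    auc: Optional[RatioWithCI] = None
    n_per_category: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        def enc(r: Optional[RatioWithCI]):
            return None if r is None else {"value": r.value, "ci": [r.ci_low, r.ci_high]}

        return {
            "sensitivity": enc(self.sensitivity),
            "specificity": enc(self.specificity),
            "accuracy": enc(self.accuracy),
            "auc": enc(self.auc),
            "n_per_category": dict(self.n_per_category),
        }


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def classify_detection_image(
    pred: Sequence[Box],
    gt: Sequence[Box],
    iou_threshold: float = DETECTION_IOU_THRESHOLD,
    image_id: str = "",
) -> DetectionOutcome:
    """Per-image TP/FP/TN/FN category from predicted and ground-truth boxes."""
    if gt:
        hit = any(iou(p, g) > iou_threshold for p in pred for g in gt)
        return DetectionOutcome(image_id, "TP" if hit else "FN")
    return DetectionOutcome(image_id, "FP" if pred else "TN")


def _proportion_ci(x: int, n: int, method: str = "wald") -> RatioWithCI:
    p = x / n
    if method == "wilson":
        z = stats.norm.ppf(1 - ALPHA / 2)
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = center - half, center + half
    else:
        half = stats.norm.ppf(1 - ALPHA / 2) * np.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    return RatioWithCI(p, max(0.0, lo), min(1.0, hi))


def detection_metrics(
    outcomes: Sequence[DetectionOutcome], ci_method: str = "wald"
) -> MetricsReport:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N,
    each with a 95% CI; a ratio with an empty denominator is reported absent."""
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    counts = {c: 0 for c in ("TP", "FP", "TN", "FN")}
    for o in outcomes:
        counts[o.category] += 1
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    n = len(outcomes)

    def ratio(x: int, d: int) -> Optional[RatioWithCI]:
        return None if d == 0 else _proportion_ci(x, d, ci_method)

    return MetricsReport(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        accuracy=ratio(tp + tn, n),
        n_per_category=counts,
    )


def _check_scores_labels(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> Tuple[RocCurve, float]:
    """Empirical ROC curve and its trapezoidal AUC.

    With ties counted as half-concordant (midranks) the trapezoidal area
    equals the Mann-Whitney concordance probability.
    """
    s, y = _check_scores_labels(scores, labels)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # collapse tied thresholds
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr), auc


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Operating point maximizing sensitivity + specificity - 1."""
    curve, _ = roc_auc(scores, labels)
    j = curve.tpr - curve.fpr
    best = int(np.argmax(j))
    t = curve.thresholds[best]
    return float(t if np.isfinite(t) else np.max(scores) + 1.0)


def _midrank_placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.r_[pos, neg])
    pos_ranks, neg_ranks = rankdata(pos), rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def _delong_auc_cov(
    scores_list: Sequence[np.ndarray], labels: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k correlated score vectors."""
    v10s, v01s = [], []
    for s in scores_list:
        v10, v01 = _midrank_placements(s, labels)
        v10s.append(v10)
        v01s.append(v01)
    v10s, v01s = np.asarray(v10s), np.asarray(v01s)
    aucs = v10s.mean(axis=1)
    m, n = v10s.shape[1], v01s.shape[1]
    s10 = np.cov(v10s, ddof=1) if m > 1 else np.zeros((len(scores_list),) * 2)
    s01 = np.cov(v01s, ddof=1) if n > 1 else np.zeros((len(scores_list),) * 2)
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def auc_ci_delong(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[float, RatioWithCI]:
    """AUC with its DeLong 95% CI, clipped to [0, 1]."""
    s, y = _check_scores_labels(scores, labels)
    aucs, cov = _delong_auc_cov([s], y)
    auc = float(aucs[0])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(1 - ALPHA / 2)
    return auc, RatioWithCI(auc, max(0.0, auc - z * se), min(1.0, auc + z * se))


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> Tuple[float, float, Optional[float], Optional[float]]:
    """DeLong comparison of two correlated AUCs on the same images.

    Returns (auc_a, auc_b, z, p_two_sided); z and p are absent (None) when
    the DeLong variance of the difference degenerates to zero, e.g. both
    models separate the classes perfectly.
    """
    a, y = _check_scores_labels(scores_a, labels)
    b, _ = _check_scores_labels(scores_b, labels)
    if int(np.sum(y == 1)) < 5 or int(np.sum(y == 0)) < 5:
        raise ValueError("need at least 5 samples per class for the DeLong test")
    aucs, cov = _delong_auc_cov([a, b], y)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if aucs[0] == aucs[1] and var <= 0:
        return float(aucs[0]), float(aucs[1]), 0.0, 1.0
    if var <= 0:
        warnings.warn("degenerate DeLong variance; p-value not defined")
        return float(aucs[0]), float(aucs[1]), None, None
    z = float((aucs[0] - aucs[1]) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), z, p


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> Tuple[float, float]:
    """Pooled two-proportion z-test, two-sided normal p-value."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not (0 <= x <= n):
            raise ValueError("counts must satisfy 0 <= x <= n, n >= 1")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion degenerate; reporting p = 1")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = float((p1 - p2) / se)
    return z, float(2 * stats.norm.sf(abs(z)))


def dataset_profile(labels_by_split: Dict[str, Sequence[int]]) -> pd.DataFrame:
    """Per-split class counts and percentages (two decimals), with totals."""
    rows = []
    for split, labels in labels_by_split.items():
        y = np.asarray(list(labels), dtype=int)
        if y.size == 0:
            raise ValueError(f"split {split!r} is empty")
        total = y.size
        for cls, name in ((0, "Non-DME"), (1, "DME")):
            count = int(np.sum(y == cls))
            rows.append(
                {
                    "split": split,
                    "class": name,
                    "n_images": count,
                    "percent": round(100.0 * count / total, 2),
                }
            )
        rows.append(
            {"split": split, "class": "Total", "n_images": total, "percent": 100.00}
        )
    return pd.DataFrame(rows)


def map_messidor_grade(grade: int) -> int:
    """Map a 3-level macular-edema risk grade to the binary DME label:
    grades 0 and 1 (no HE, or HE beyond 1DD) are non-DME; grade 2 is DME."""
    if grade not in (0, 1, 2):
        raise ValueError(f"grade must be 0, 1, or 2; got {grade}")
    return int(grade == 2)
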