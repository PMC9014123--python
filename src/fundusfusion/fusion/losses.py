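"""The fused training objective: focal classification term plus detector loss.

The joint loss is ``E_loss = omega_ob * E_ob + omega_cl * E_cl`` where
``E_ob`` is the detection-head loss (anchor-level focal classification plus
Huber box regression, normalised by the matched-anchor count) and ``E_cl`` is
the image-level binary focal term ``-alpha * (1 - p_t)^gamma * ln(p_t)`` with
``p_t = p`` for a DME image and ``1 - p`` otherwise.  Defaults follow the
standard focal-loss setting ``alpha = 0.25, gamma = 2`` and the retrained
balance ``omega_ob = 0.5, omega_cl = 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..geometry import Box
from .anchors import AnchorGrid, assign_targets
from .autograd import Tensor

__all__ = [
    "FocalParams",
    "LossWeights",
    "LossBreakdown",
    "ClassificationOutput",
    "pt_transform",
    "focal_term",
    "combined_loss",
    "detector_loss",
    "focal_loss_tensor",
    "huber_loss_tensor",
    "detector_loss_tensor",
]

EPS = 1e-7
HUBER_DELTA = 1.0


@dataclass(frozen=True)
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be non-negative")


@dataclass(frozen=True)
class LossWeights:
    omega_ob: float = 0.5
    omega_cl: float = 100.0

    def __post_init__(self) -> None:
        if self.omega_ob <= 0 or self.omega_cl <= 0:
            raise ValueError("loss weights must be strictly positive")


@dataclass(frozen=True)
class LossBreakdown:
    e_ob: float
    e_cl: float
    e_total: float


@dataclass(frozen=True)
class ClassificationOutput:
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"probability must be in [0, 1], got {self.p}")


def pt_transform(p: float, label: int) -> float:
    """``p_t``: the probability assigned to the true class."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return p if label else 1.0 - p


def focal_term(p: float, label: int, fp: FocalParams = FocalParams()) -> float:
    """Scalar binary focal loss ``-alpha * (1 - p_t)^gamma * ln(p_t)``.

    ``p_t`` is clamped below at 1e-7 for numerical safety; a perfectly
    confident correct prediction (``p_t = 1``) gives exactly zero.
    """
    pt = max(pt_transform(p, label), EPS)
    return -fp.alpha * (1.0 - pt) ** fp.gamma * math.log(pt)


def combined_loss(e_ob: float, e_cl: float, w: LossWeights = LossWeights()) -> LossBreakdown:
    """Linear combination of the detector and classifier losses."""
    if e_cl < 0:
        raise ValueError("classification focal term cannot be negative")
    return LossBreakdown(e_ob=e_ob, e_cl=e_cl, e_total=w.omega_ob * e_ob + w.omega_cl * e_cl)


def detector_loss(
    cls_probs: np.ndarray,
    reg_offsets: np.ndarray,
    gt_boxes: Sequence[Box],
    grid: AnchorGrid,
    gt_classes: Optional[Sequence[int]] = None,
    fp: FocalParams = FocalParams(),
) -> float:
    """Detection-head loss ``E_ob`` from per-anchor predictions.

    ``cls_probs`` is (A, K) predicted class probabilities, ``reg_offsets`` is
    (A, 4) predicted encoded offsets.  The loss is the anchor-level focal
    classification loss over non-ignored anchors plus Huber regression over
    positive anchors, both divided by the matched-anchor count (minimum 1).
    An empty ground truth yields a pure background classification loss.
    """
    cls_probs = np.asarray(cls_probs, dtype=float)
    reg_offsets = np.asarray(reg_offsets, dtype=float)
    k = cls_probs.shape[1]
    if gt_classes is None:
        gt_classes = [0] * len(gt_boxes)
    cls_t, reg_t, state = assign_targets(grid, list(gt_boxes), list(gt_classes), k)

    valid = (state >= 0)[:, None]
    p = np.clip(cls_probs, EPS, 1.0 - EPS)
    pt = np.where(cls_t == 1.0, p, 1.0 - p)
    alpha_t = np.where(cls_t == 1.0, fp.alpha, 1.0 - fp.alpha)
    focal = -alpha_t * (1.0 - pt) ** fp.gamma * np.log(pt)
    n_pos = max(1.0, float((state == 1).sum()))
    cls_loss = float((focal * valid).sum() / n_pos)

    pos = state == 1
    diff = reg_offsets[pos] - reg_t[pos]
    a = np.abs(diff)
    huber = np.where(a < HUBER_DELTA, 0.5 * diff ** 2, HUBER_DELTA * (a - 0.5 * HUBER_DELTA))
    reg_loss = float(huber.sum() / n_pos)
    return cls_loss + reg_loss


# ---- tensor-level versions used by the training graph ---------------------


def focal_loss_tensor(logits: Tensor, targets: np.ndarray, valid_mask: np.ndarray,
                      fp: FocalParams, normalizer: float) -> Tensor:
    """Anchor focal loss from raw logits; targets/masks are constants."""
    p = logits.sigmoid().clamp(EPS, 1.0 - EPS)
    pt = p * targets + (1.0 - p) * (1.0 - targets)
    alpha_t = fp.alpha * targets + (1.0 - fp.alpha) * (1.0 - targets)
    loss = -1.0 * alpha_t * (1.0 - pt).pow(fp.gamma) * pt.log()
    return (loss * valid_mask).sum() * (1.0 / normalizer)


def huber_loss_tensor(pred: Tensor, target: np.ndarray, pos_mask: np.ndarray,
                      normalizer: float, delta: float = HUBER_DELTA) -> Tensor:
    diff = pred - target
    a = np.abs(diff.data)
    quad = a < delta
    loss = quad * 0.5 * diff * diff + (~quad) * delta * (diff.abs() - 0.5 * delta)
    return (loss * pos_mask).sum() * (1.0 / normalizer)


def detector_loss_tensor(
    cls_logits: Tensor,  # (N, A, K)
    reg_preds: Tensor,  # (N, A, 4)
    cls_targets: np.ndarray,
    reg_targets: np.ndarray,
    states: np.ndarray,  # (N, A)
    fp: FocalParams,
) -> Tensor:
    """Batch detector loss matching :func:`detector_loss` image by image."""
    n = states.shape[0]
    valid = (states >= 0)[:, :, None].astype(float)
    pos = (states == 1)[:, :, None].astype(float)
    n_pos = np.maximum(1.0, (states == 1).sum(axis=1))  # per image
    inv = (1.0 / n_pos)[:, None, None]
    cls_loss = focal_loss_tensor(cls_logits, cls_targets, valid * inv, fp, normalizer=1.0)
    reg_loss = huber_loss_tensor(reg_preds, reg_targets, pos * inv, normalizer=1.0)
    return (cls_loss + reg_loss) * (1.0 / float(n))
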