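"""Multi-annotator bounding-box consensus for hard-exudate ground truth.

Three ophthalmologist-style annotation sets are fused pairwise: boxes of two
annotators are matched one-to-one (maximum-total-IoU assignment restricted to
pairs with IoU strictly above the threshold, default 0.15); for each matched
pair the box with the larger area is kept verbatim, and every unmatched box
from either set is retained.  The third annotator is then merged against the
result of the first two, yielding the final ground truth.

An IoU exactly equal to the threshold does not match (both boxes are kept),
and an equal-area matched pair keeps the box from the first argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box, area, iou

__all__ = ["AnnotationSet", "merge_pair", "consensus_gt", "DEFAULT_IOU_THRESHOLD"]

DEFAULT_IOU_THRESHOLD = 0.15


@dataclass
class AnnotationSet:
    """One annotator's hard-exudate boxes for one image. May be empty."""

    image_id: str
    annotator_id: str
    boxes: List[Box] = field(default_factory=list)


def _sorted_reading_order(boxes: Sequence[Box]) -> List[Box]:
    return sorted(boxes, key=lambda b: (b.y_min, b.x_min, b.y_max, b.x_max))


def _match_above_threshold(
    boxes_a: Sequence[Box], boxes_b: Sequence[Box], iou_threshold: float
) -> List[tuple]:
    """One-to-one matching maximizing total IoU over pairs with IoU > threshold.

    Returns (i, j, iou) triples. Solved as a rectangular assignment problem;
    pairs at or below the threshold carry zero weight and are discarded from
    the solution, so they can never force a match.
    """
    if not boxes_a or not boxes_b:
        return []
    w = np.zeros((len(boxes_a), len(boxes_b)))
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            v = iou(a, b)
            if v > iou_threshold:
                w[i, j] = v
    rows, cols = linear_sum_assignment(w, maximize=True)
    return [(i, j, w[i, j]) for i, j in zip(rows, cols) if w[i, j] > iou_threshold]


def merge_pair(
    a: AnnotationSet, b: AnnotationSet, iou_threshold: float = DEFAULT_IOU_THRESHOLD
) -> AnnotationSet:
    """Fuse two annotators' box sets into one.

    Matched pairs (IoU > threshold) keep the larger-area box; unmatched boxes
    from both sets are retained.  Output boxes are sorted by (y_min, x_min).
    """
    if a.image_id != b.image_id:
        raise ValueError(f"mismatched image ids: {a.image_id!r} vs {b.image_id!r}")
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")

    matches = _match_above_threshold(a.boxes, b.boxes, iou_threshold)
    matched_a = {i for i, _, _ in matches}
    matched_b = {j for _, j, _ in matches}

    kept: List[Box] = []
    for i, j, _ in matches:
        box_a, box_b = a.boxes[i], b.boxes[j]
        # equal area keeps the first argument's box
        kept.append(box_b if area(box_b) > area(box_a) else box_a)
    kept.extend(box for i, box in enumerate(a.boxes) if i not in matched_a)
    kept.extend(box for j, box in enumerate(b.boxes) if j not in matched_b)

    return AnnotationSet(
        image_id=a.image_id,
        annotator_id=f"merge({a.annotator_id},{b.annotator_id})",
        boxes=_sorted_reading_order(kept),
    )


def consensus_gt(
    sets: Sequence[AnnotationSet], iou_threshold: float = DEFAULT_IOU_THRESHOLD
) -> AnnotationSet:
    """Final ground truth from exactly three annotators: merge the first two,
    then merge that result with the third."""
    if len(sets) != 3:
        raise ValueError(f"exactly three annotation sets required, got {len(sets)}")
    first = merge_pair(sets[0], sets[1], iou_threshold)
    final = merge_pair(first, sets[2], iou_threshold)
    final.annotator_id = "consensus"
    return final
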