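"""Anchor grids, target assignment, box encoding/decoding, and NMS.

Anchors are square (one aspect ratio), three octave scales per pyramid level
(2^0, 2^(1/3), 2^(2/3) times the level's base size).  Assignment follows the
conventional focal-detector rule: an anchor is positive when its best IoU
with a ground-truth box reaches 0.5, negative below 0.4, ignored in between;
in addition every ground-truth box claims its single best-overlapping anchor
so that small lesions falling between grid cells still receive a positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..geometry import Box

__all__ = ["AnchorGrid", "build_anchors", "assign_targets", "decode_boxes", "nms"]

SCALES = (1.0, 2.0 ** (1.0 / 3.0), 2.0 ** (2.0 / 3.0))
POS_IOU = 0.5
NEG_IOU = 0.4


@dataclass
class AnchorGrid:
    """All anchors of a model input, flattened level-major as (A, 4) corners."""

    boxes: np.ndarray  # (A, 4) x_min, y_min, x_max, y_max
    centers: np.ndarray  # (A, 2)
    sizes: np.ndarray  # (A, 2) width, height
    level_slices: List[slice]

    def __len__(self) -> int:
        return self.boxes.shape[0]


def build_anchors(
    input_size: int,
    pyramid_levels: Sequence[int],
    base_scale: float = 1.0,
    scales: Sequence[float] = SCALES,
) -> AnchorGrid:
    """Anchor grid for a square input; level ``l`` has stride ``2**l``."""
    all_boxes, slices = [], []
    start = 0
    for level in pyramid_levels:
        stride = 2 ** level
        g = input_size // stride
        cs = (np.arange(g) + 0.5) * stride
        cxs, cys = np.meshgrid(cs, cs)  # row-major: y outer
        sizes = np.asarray(scales) * base_scale * stride
        # per cell: scales vary fastest, matching head channel layout
        cx = np.repeat(cxs.reshape(-1), len(sizes))
        cy = np.repeat(cys.reshape(-1), len(sizes))
        sz = np.tile(sizes, g * g)
        boxes = np.stack(
            [cx - sz / 2, cy - sz / 2, cx + sz / 2, cy + sz / 2], axis=1
        )
        all_boxes.append(boxes)
        slices.append(slice(start, start + boxes.shape[0]))
        start += boxes.shape[0]
    boxes = np.concatenate(all_boxes, axis=0)
    centers = np.stack(
        [(boxes[:, 0] + boxes[:, 2]) / 2, (boxes[:, 1] + boxes[:, 3]) / 2], axis=1
    )
    sizes = np.stack([boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1]], axis=1)
    return AnchorGrid(boxes=boxes, centers=centers, sizes=sizes, level_slices=slices)


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) corner arrays."""
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(inter > 0, inter / union, 0.0)


def boxes_to_array(boxes: Sequence[Box]) -> np.ndarray:
    if not boxes:
        return np.zeros((0, 4))
    return np.asarray([[b.x_min, b.y_min, b.x_max, b.y_max] for b in boxes])


def assign_targets(
    grid: AnchorGrid,
    gt_boxes: Sequence[Box],
    gt_classes: Sequence[int],
    num_classes: int,
    pos_iou: float = POS_IOU,
    neg_iou: float = NEG_IOU,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-anchor classification targets, regression targets, and masks.

    Returns ``(cls_target, reg_target, anchor_state)`` where ``cls_target`` is
    (A, K) one-hot, ``reg_target`` is (A, 4) encoded offsets, and
    ``anchor_state`` is (A,) with 1 positive, 0 negative, -1 ignored.
    """
    a = len(grid)
    cls_target = np.zeros((a, num_classes))
    reg_target = np.zeros((a, 4))
    if not gt_boxes:
        return cls_target, reg_target, np.zeros(a)

    gt = boxes_to_array(gt_boxes)
    iou = _iou_matrix(grid.boxes, gt)  # (A, G)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(a), best_gt]

    state = np.full(a, -1.0)
    state[best_iou < neg_iou] = 0.0
    state[best_iou >= pos_iou] = 1.0
    # every gt claims its best anchor (low-quality fallback)
    forced = iou.argmax(axis=0)
    for g_idx, a_idx in enumerate(forced):
        if iou[a_idx, g_idx] > 0:
            state[a_idx] = 1.0
            best_gt[a_idx] = g_idx

    pos = state == 1.0
    idx = best_gt[pos]
    gw = gt[idx, 2] - gt[idx, 0]
    gh = gt[idx, 3] - gt[idx, 1]
    gx = (gt[idx, 0] + gt[idx, 2]) / 2
    gy = (gt[idx, 1] + gt[idx, 3]) / 2
    aw, ah = grid.sizes[pos, 0], grid.sizes[pos, 1]
    ax, ay = grid.centers[pos, 0], grid.centers[pos, 1]
    reg_target[pos, 0] = (gx - ax) / aw
    reg_target[pos, 1] = (gy - ay) / ah
    reg_target[pos, 2] = np.log(gw / aw)
    reg_target[pos, 3] = np.log(gh / ah)
    classes = np.asarray(list(gt_classes), dtype=int)
    cls_target[pos, classes[idx]] = 1.0
    return cls_target, reg_target, state


def decode_boxes(
    grid: AnchorGrid, offsets: np.ndarray, input_size: Optional[int] = None
) -> np.ndarray:
    """Invert the offset encoding; optionally clip to the image square."""
    cx = grid.centers[:, 0] + offsets[:, 0] * grid.sizes[:, 0]
    cy = grid.centers[:, 1] + offsets[:, 1] * grid.sizes[:, 1]
    w = grid.sizes[:, 0] * np.exp(np.clip(offsets[:, 2], -4.0, 4.0))
    h = grid.sizes[:, 1] * np.exp(np.clip(offsets[:, 3], -4.0, 4.0))
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
    if input_size is not None:
        boxes = np.clip(boxes, 0.0, float(input_size))
    return boxes


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.5) -> List[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep: List[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        iou = _iou_matrix(boxes[i: i + 1], boxes[rest])[0]
        order = rest[iou <= iou_threshold]
    return keep
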