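"""Three-annotator bounding-box consensus against an exhaustive oracle."""

import itertools
from typing import List, Sequence, Tuple

import pytest

from fundusfusion.consensus import AnnotationSet, consensus_gt, merge_pair
from fundusfusion.geometry import Box, area, iou
from .conftest import random_box


def ann(boxes, image_id="img", annotator="a") -> AnnotationSet:
    return AnnotationSet(image_id, annotator, list(boxes))


def corner_sets(s: AnnotationSet) -> List[Tuple[float, float, float, float]]:
    return sorted((b.x_min, b.y_min, b.x_max, b.y_max) for b in s.boxes)


def oracle_merge(boxes_a: Sequence[Box], boxes_b: Sequence[Box],
                 thr: float = 0.15) -> List[Box]:
    """Exhaustive enumeration over all one-to-one matchings restricted to
    pairs with IoU above threshold, maximizing total IoU; matched pairs keep
    the larger box (first set wins ties), unmatched boxes are retained."""
    na, nb = len(boxes_a), len(boxes_b)
    best_total, best_match = -1.0, []
    idx_b = range(nb)
    for r in range(min(na, nb) + 1):
        for rows in itertools.combinations(range(na), r):
            for cols in itertools.permutations(idx_b, r):
                pairs = list(zip(rows, cols))
                if any(iou(boxes_a[i], boxes_b[j]) <= thr for i, j in pairs):
                    continue
                total = sum(iou(boxes_a[i], boxes_b[j]) for i, j in pairs)
                if total > best_total + 1e-12:
                    best_total, best_match = total, pairs
    kept = []
    ma = {i for i, _ in best_match}
    mb = {j for _, j in best_match}
    for i, j in best_match:
        a, b = boxes_a[i], boxes_b[j]
        kept.append(b if area(b) > area(a) else a)
    kept.extend(b for k, b in enumerate(boxes_a) if k not in ma)
    kept.extend(b for k, b in enumerate(boxes_b) if k not in mb)
    return kept


class TestMergePair:
    def test_both_empty(self):
        assert merge_pair(ann([]), ann([])).boxes == []

    def test_overlapping_keeps_larger(self):
        a, b = Box(0, 0, 10, 10), Box(2, 2, 14, 14)
        assert iou(a, b) == pytest.approx(64 / 180)
        out = merge_pair(ann([a]), ann([b]))
        assert len(out.boxes) == 1
        assert out.boxes[0].geometry_equal(b)  # area 144 beats 100

    def test_disjoint_keeps_both(self):
        a, b = Box(0, 0, 10, 10), Box(30, 30, 40, 40)
        out = merge_pair(ann([a]), ann([b]))
        assert len(out.boxes) == 2

    def test_iou_exactly_threshold_keeps_both(self):
        # intersection 30, union 200 -> IoU exactly 0.15: no match
        a, b = Box(0, 0, 10, 3), Box(0, 0, 10, 20)
        assert iou(a, b) == pytest.approx(0.15, abs=1e-12)
        out = merge_pair(ann([a]), ann([b]))
        assert len(out.boxes) == 2

    def test_equal_area_tie_keeps_first_argument(self):
        a = Box(0, 0, 10, 10, category="HE")
        b = Box(1, 0, 11, 10, category="HE")
        out = merge_pair(ann([a], annotator="first"), ann([b], annotator="second"))
        assert len(out.boxes) == 1
        assert out.boxes[0].geometry_equal(a)

    def test_mismatched_image_rejected(self):
        with pytest.raises(ValueError):
            merge_pair(ann([], image_id="x"), ann([], image_id="y"))

    def test_empty_identity(self, rng):
        boxes = [random_box(rng) for _ in range(4)]
        out = merge_pair(ann(boxes), ann([]))
        assert corner_sets(out) == corner_sets(ann(boxes))

    def test_idempotent(self, rng):
        boxes = [random_box(rng) for _ in range(5)]
        out = merge_pair(ann(boxes), ann(boxes))
        assert corner_sets(out) == corner_sets(ann(boxes))

    def test_order_invariant_for_one_to_one_overlaps(self, rng):
        """When every box overlaps at most one box of the other set, the
        merged geometry does not depend on argument order."""
        for trial in range(30):
            a = [random_box(rng, hi=200) for _ in range(3)]
            # displaced copies overlap only their source box
            b = [Box(x.x_min + 2, x.y_min + 2, x.x_max + 3, x.y_max + 1)
                 for x in a]
            ab = merge_pair(ann(a), ann(b))
            ba = merge_pair(ann(b), ann(a))
            assert corner_sets(ab) == corner_sets(ba)


class TestConsensusGT:
    def test_all_empty(self):
        assert consensus_gt([ann([]), ann([]), ann([])]).boxes == []

    def test_three_identical_single_boxes(self):
        b = Box(5, 5, 25, 25, category="HE")
        out = consensus_gt([ann([b]), ann([b]), ann([b])])
        assert len(out.boxes) == 1
        assert out.boxes[0].geometry_equal(b)

    def test_two_step_merge_by_hand(self):
        # A overlaps B (B larger); C is far from both -> {B, C}
        A = Box(0, 0, 10, 10)
        B = Box(1, 1, 13, 13)
        C = Box(50, 50, 60, 60)
        assert iou(A, B) > 0.15 and iou(B, C) <= 0.15
        out = consensus_gt([ann([A]), ann([B]), ann([C])])
        assert corner_sets(out) == corner_sets(ann([B, C]))

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            consensus_gt([ann([]), ann([])])

    def test_matches_exhaustive_oracle(self, rng):
        """500 random instances with up to 3 boxes per annotator: the two
        pairwise merges reproduce exhaustive matching enumeration."""
        for trial in range(500):
            sets = [
                [random_box(rng, hi=60, max_size=30) for _ in range(rng.integers(0, 4))]
                for _ in range(3)
            ]
            expected_first = oracle_merge(sets[0], sets[1])
            expected = oracle_merge(expected_first, sets[2])
            got = consensus_gt([ann(s) for s in sets])
            assert corner_sets(got) == corner_sets(ann(expected)), f"trial {trial}"

    def test_no_synthesized_geometry(self, rng):
        for _ in range(50):
            sets = [
                [random_box(rng, hi=50) for _ in range(rng.integers(0, 4))]
                for _ in range(3)
            ]
            inputs = {c for s in sets for c in corner_sets(ann(s))}
            out = consensus_gt([ann(s) for s in sets])
            assert len(out.boxes) <= sum(len(s) for s in sets)
            assert all(c in inputs for c in corner_sets(out))
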