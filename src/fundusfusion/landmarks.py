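"""Anatomical landmarks (optic disc, macula) and the geometric DME rule.

Following the ETDRS-derived criterion, an image is labelled DME exactly when
some hard exudate lies at or within one disc diameter (1DD) of the center of
the macula.  Distances are measured from the macula center to the nearest
point of each HE box, and the disc diameter of a bounding box is the mean of
its width and height (optic discs are near-circular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Protocol, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw

from .geometry import Box, Category, Point, distance_point_to_box
from .preprocessing import ImageRecord

__all__ = [
    "LandmarkSet",
    "UngradableImageError",
    "Detector",
    "detect_landmarks",
    "disc_diameter",
    "macula_center",
    "dme_rule",
    "render_overlay",
]

logger = logging.getLogger(__name__)

HE_COLOR = (40, 80, 255)  # blue
LANDMARK_COLOR = (255, 255, 255)  # white


class UngradableImageError(ValueError):
    """Raised when the DME rule is applied without the landmarks it needs."""


@dataclass
class LandmarkSet:
    """At most one optic disc and one macula per image, with confidences."""

    disc_box: Optional[Box] = None
    macula_box: Optional[Box] = None
    disc_confidence: Optional[float] = None
    macula_confidence: Optional[float] = None


class Detector(Protocol):
    """Anything that maps an image to scored, categorised boxes qualifies
    (the single-task instance of the fusion detection head does)."""

    def detect(self, img: ImageRecord) -> List[Box]: ...


def detect_landmarks(detector: Detector, img: ImageRecord) -> LandmarkSet:
    """Run a landmark detector and keep the highest-confidence disc and macula.

    Absence is signalled by ``None`` fields, never by a crash.
    """
    detections = detector.detect(img)
    result = LandmarkSet()
    for cat in (Category.OPTIC_DISC, Category.MACULA):
        candidates = [b for b in detections if b.category == cat]
        if not candidates:
            continue
        best = max(candidates, key=lambda b: b.score if b.score is not None else 0.0)
        if cat == Category.OPTIC_DISC:
            result.disc_box, result.disc_confidence = best, best.score
        else:
            result.macula_box, result.macula_confidence = best, best.score
    return result


def disc_diameter(disc_box: Box) -> float:
    """Disc diameter (1DD) from its bounding box: mean of width and height."""
    return (disc_box.width + disc_box.height) / 2.0


def macula_center(macula_box: Box) -> Point:
    """Macula center as the box centroid."""
    return macula_box.center


def dme_rule(he_boxes: Sequence[Box], disc_box: Optional[Box], macula_box: Optional[Box]) -> int:
    """DME label: 1 iff any HE box lies at or within 1DD of the macula center.

    The boundary is inclusive ("at or within"), distances are taken to the
    nearest point of each HE box, and an image without HE is non-DME.  Missing
    landmarks make the image ungradable (an explicit error, never a silent 0).
    """
    if disc_box is None or macula_box is None:
        raise UngradableImageError("optic disc and macula are required to grade DME")
    if not he_boxes:
        return 0
    center = macula_center(macula_box)
    dd = disc_diameter(disc_box)
    return int(any(distance_point_to_box(center, b) <= dd for b in he_boxes))


def render_overlay(
    img: ImageRecord,
    he_boxes: Sequence[Box] = (),
    landmarks: Optional[LandmarkSet] = None,
    line_width: int = 2,
) -> ImageRecord:
    """Composite HE boxes (blue), the optic-disc box (white) and the 1DD circle
    (white, centered on the macula) onto a copy of the image."""
    im = Image.fromarray(img.pixels.copy())
    draw = ImageDraw.Draw(im)
    for b in he_boxes:
        draw.rectangle([b.x_min, b.y_min, b.x_max - 1, b.y_max - 1], outline=HE_COLOR, width=line_width)
    if landmarks is not None:
        if landmarks.disc_box is not None:
            d = landmarks.disc_box
            draw.rectangle(
                [d.x_min, d.y_min, d.x_max - 1, d.y_max - 1],
                outline=LANDMARK_COLOR,
                width=line_width,
            )
        if landmarks.macula_box is not None and landmarks.disc_box is not None:
            c = macula_center(landmarks.macula_box)
            r = disc_diameter(landmarks.disc_box)
            draw.ellipse(
                [c.x - r, c.y - r, c.x + r, c.y + r],
                outline=LANDMARK_COLOR,
                width=line_width,
            )
        elif landmarks.macula_box is not None:
            logger.warning("macula present but disc absent: 1DD circle radius unknown, skipped")
    return ImageRecord(image_id=img.image_id, pixels=np.asarray(im), source_path=img.source_path)
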