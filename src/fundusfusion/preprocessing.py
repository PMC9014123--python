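"""Fundus-image preprocessing: border crop, resize, and flip augmentation.

A 45-degree-FOV fundus photograph is a bright circular region on a nearly
black field.  Preprocessing crops each image to the tight bounding box of the
non-black region, resamples to a square model input (bilinear), and maps the
bounding-box annotations through the same affine transform so that predictions
can later be mapped back to source coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .geometry import AffineTransform, Box, transform_box

__all__ = [
    "ImageRecord",
    "find_fundus_bbox",
    "crop_and_resize",
    "augment_flip",
    "flip_horizontal",
    "flip_vertical",
    "load_image",
    "save_image",
]

logger = logging.getLogger(__name__)

DEFAULT_BLACK_THRESHOLD = 10.0
DEFAULT_INPUT_SIZE = 640  # model input side used at full scale


@dataclass
class ImageRecord:
    """An 8-bit RGB image with an identifier."""

    image_id: str
    pixels: np.ndarray  # H x W x 3 uint8
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("image smaller than 32x32")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def load_image(path: str, image_id: Optional[str] = None) -> ImageRecord:
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return ImageRecord(image_id=image_id or str(path), pixels=px, source_path=str(path))


def save_image(img: ImageRecord, path: str) -> None:
    Image.fromarray(img.pixels).save(path)


def find_fundus_bbox(img: ImageRecord, black_threshold: float = DEFAULT_BLACK_THRESHOLD) -> Box:
    """Tight bounding box of pixels whose channel-mean grayscale exceeds the
    black threshold; falls back to the full-image box when nothing does."""
    gray = img.pixels.mean(axis=2)
    mask = gray > black_threshold
    if not mask.any():
        return Box(0.0, 0.0, float(img.width), float(img.height))
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return Box(
        float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)
    )


def crop_and_resize(
    img: ImageRecord,
    boxes: Sequence[Box] = (),
    target: int = DEFAULT_INPUT_SIZE,
    black_threshold: float = DEFAULT_BLACK_THRESHOLD,
) -> Tuple[ImageRecord, List[Box], AffineTransform]:
    """Crop to the fundus region then resample to ``target x target``.

    The tight crop may be non-square, so the two axes may scale differently.
    Boxes fully outside the crop are dropped with a warning; the transform is
    returned so predictions can be inverse-mapped to source coordinates.
    """
    if target < 32:
        raise ValueError("target size must be >= 32")
    fb = find_fundus_bbox(img, black_threshold)
    x0, y0, x1, y1 = (int(round(v)) for v in (fb.x_min, fb.y_min, fb.x_max, fb.y_max))
    crop = img.pixels[y0:y1, x0:x1]
    ch, cw = crop.shape[:2]
    t = AffineTransform(
        scale_x=target / cw, scale_y=target / ch, offset_x=float(x0), offset_y=float(y0)
    )

    if (cw, ch) == (target, target):
        out_px = crop.copy()
    else:
        out_px = np.asarray(
            Image.fromarray(crop).resize((target, target), Image.BILINEAR)
        )

    out_boxes: List[Box] = []
    for b in boxes:
        if b.x_max <= x0 or b.x_min >= x1 or b.y_max <= y0 or b.y_min >= y1:
            logger.warning(
                "box %s of image %s falls outside the fundus crop; dropped", b, img.image_id
            )
            continue
        out_boxes.append(transform_box(b, t))

    return ImageRecord(image_id=img.image_id, pixels=out_px), out_boxes, t


def flip_horizontal(img: ImageRecord, boxes: Sequence[Box]) -> Tuple[ImageRecord, List[Box]]:
    """Mirror image and boxes about the vertical midline."""
    w = float(img.width)
    out = ImageRecord(img.image_id, img.pixels[:, ::-1].copy(), img.source_path)
    flipped = [
        Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max, b.score, b.category) for b in boxes
    ]
    return out, flipped


def flip_vertical(img: ImageRecord, boxes: Sequence[Box]) -> Tuple[ImageRecord, List[Box]]:
    """Mirror image and boxes about the horizontal midline."""
    h = float(img.height)
    out = ImageRecord(img.image_id, img.pixels[::-1, :].copy(), img.source_path)
    flipped = [
        Box(b.x_min, h - b.y_max, b.x_max, h - b.y_min, b.score, b.category) for b in boxes
    ]
    return out, flipped


def augment_flip(
    img: ImageRecord, boxes: Sequence[Box], rng_seed: int
) -> Tuple[ImageRecord, List[Box]]:
    """Randomly flip horizontally and, independently, vertically (p = 0.5 each)."""
    rng = np.random.default_rng(rng_seed)
    boxes = list(boxes)
    if rng.random() < 0.5:
        img, boxes = flip_horizontal(img, boxes)
    if rng.random() < 0.5:
        img, boxes = flip_vertical(img, boxes)
    return img, boxes
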