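"""File formats: COCO-style annotation JSON, label CSV, detection JSON.

Annotation records are one JSON object per image and annotator::

    {"image_id": "...", "annotator_id": "...",
     "boxes": [{"x": .., "y": .., "width": .., "height": .., "category": "HE",
                "score": ..?}, ...]}

Files store ``(x, y, width, height)``; in memory everything is corner-form
:class:`~fundusfusion.geometry.Box`.  Image-level labels travel as a
two-column CSV ``image_id,label``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .consensus import AnnotationSet
from .geometry import Box

__all__ = [
    "box_to_record",
    "record_to_box",
    "write_annotation_set",
    "read_annotation_set",
    "write_detections",
    "read_detections",
    "write_labels_csv",
    "read_labels_csv",
]

PathLike = Union[str, Path]


def box_to_record(b: Box) -> Dict:
    rec = {
        "x": b.x_min,
        "y": b.y_min,
        "width": b.width,
        "height": b.height,
        "category": b.category,
    }
    if b.score is not None:
        rec["score"] = b.score
    return rec


def record_to_box(rec: Dict) -> Box:
    return Box(
        x_min=float(rec["x"]),
        y_min=float(rec["y"]),
        x_max=float(rec["x"]) + float(rec["width"]),
        y_max=float(rec["y"]) + float(rec["height"]),
        score=float(rec["score"]) if "score" in rec and rec["score"] is not None else None,
        category=rec.get("category"),
    )


def write_annotation_set(ann: AnnotationSet, path: PathLike) -> None:
    payload = {
        "image_id": ann.image_id,
        "annotator_id": ann.annotator_id,
        "boxes": [box_to_record(b) for b in ann.boxes],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation_set(path: PathLike) -> AnnotationSet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed annotation JSON at line {e.lineno}: {e.msg}") from e
    try:
        return AnnotationSet(
            image_id=payload["image_id"],
            annotator_id=payload.get("annotator_id", "unknown"),
            boxes=[record_to_box(r) for r in payload["boxes"]],
        )
    except KeyError as e:
        raise ValueError(f"{path}: missing annotation field {e}") from e


def write_detections(detections: Dict[str, Sequence[Box]], path: PathLike,
                     meta: Optional[Dict] = None) -> None:
    """Per-image detection lists with scores, plus an optional metadata block
    (config hash, seeds, transforms) embedded alongside."""
    payload = {
        "meta": meta or {},
        "images": {
            image_id: [box_to_record(b) for b in boxes]
            for image_id, boxes in detections.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections(path: PathLike) -> Dict[str, List[Box]]:
    payload = json.loads(Path(path).read_text())
    return {
        image_id: [record_to_box(r) for r in recs]
        for image_id, recs in payload["images"].items()
    }


def write_labels_csv(labels: Dict[str, int], path: PathLike) -> None:
    df = pd.DataFrame(sorted(labels.items()), columns=["image_id", "label"])
    df.to_csv(path, index=False)


def read_labels_csv(path: PathLike) -> Dict[str, int]:
    df = pd.read_csv(path, dtype={"image_id": str})
    return dict(zip(df["image_id"], df["label"].astype(int)))
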