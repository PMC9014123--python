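"""Synthetic fundus scenes with known geometry and simulated annotators.

The generator emulates a 45-degree-FOV fundus photograph as a caricature: a
near-black field, a bright circular fundus region, one bright elliptical optic
disc, a darker macula roughly two disc diameters temporal to the disc, and a
configurable number of small bright hard-exudate (HE) blobs.  The DME label is
not drawn independently of the geometry: lesions are placed inside or outside
the 1-disc-diameter circle around the macula center according to the sampled
label, and the stored label is then *recomputed* from the placed boxes with
the geometric rule, so truth and geometry can never disagree.

Lesion contrast is deliberately high so that a small CPU-trainable network can
succeed; the scenes verify mechanisms, they do not emulate clinical imagery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .consensus import AnnotationSet, consensus_gt
from .geometry import Box, Category, Point
from .landmarks import dme_rule
from .preprocessing import ImageRecord, save_image
from . import io as ffio

__all__ = [
    "GeneratorParams",
    "SceneTruth",
    "sample_scene_truth",
    "render_scene",
    "generate_scene",
    "simulate_annotators",
    "generate_dataset",
]

_REFERENCE_SIZE = 256  # pixel defaults below are stated at this image size


@dataclass
class GeneratorParams:
    """Knobs of the synthetic scene generator.

    Pixel-valued defaults are stated for 256x256 scenes; use
    :meth:`for_image_size` to rescale them consistently.  The default DME
    prevalence of 0.42 mirrors a training population in which DME is common
    but not the majority class; among non-DME scenes the lesion count is
    drawn from ``he_count_range`` (its lower bound of 0 yields lesion-free
    images, which the image-level detection specificity needs).
    """

    image_size: int = 256
    dme_prevalence: float = 0.42
    he_count_range: Tuple[int, int] = (0, 4)
    he_size_range: Tuple[float, float] = (10.0, 26.0)
    annotator_jitter_sd: float = 2.0
    annotator_miss_rate: float = 0.1
    annotator_spurious_rate: float = 0.1
    background_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 to fit disc, macula and lesions")
        for name in ("dme_prevalence", "annotator_miss_rate", "annotator_spurious_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.he_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"he_count_range must be a non-empty interval, got {self.he_count_range}")
        slo, shi = self.he_size_range
        if slo < 2 or shi < slo:
            raise ValueError(f"he_size_range must be >= 2 px and non-empty, got {self.he_size_range}")
        if self.background_noise_sd < 0 or self.annotator_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def for_image_size(cls, image_size: int, **overrides) -> "GeneratorParams":
        """Defaults with every pixel-valued field rescaled to ``image_size``."""
        s = image_size / _REFERENCE_SIZE
        base = cls(image_size=image_size,
                   he_size_range=(max(3.0, 10.0 * s), max(5.0, 26.0 * s)),
                   annotator_jitter_sd=2.0 * s)
        for k, v in overrides.items():
            setattr(base, k, v)
        base.__post_init__()
        return base


@dataclass
class SceneTruth:
    """Exact ground truth of one rendered scene."""

    image_id: str
    disc_box: Box
    macula_box: Box
    he_boxes: List[Box] = field(default_factory=list)
    dme_label: int = 0
    fundus_center: Optional[Point] = None
    fundus_radius: Optional[float] = None


def _ellipse_box(cx: float, cy: float, w: float, h: float, category: str) -> Box:
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, category=category)


def sample_scene_truth(
    params: GeneratorParams, rng: np.random.Generator, image_id: str = "scene"
) -> SceneTruth:
    """Sample disc/macula/lesion geometry and the implied DME label.

    Lesion placement keeps a margin around the 1DD boundary (nearest point at
    most 0.85 DD inside, at least 1.15 DD outside) so annotator jitter cannot
    straddle the rule; the stored label is recomputed with ``dme_rule``.
    """
    S = params.image_size
    cx = cy = S / 2.0
    radius = 0.47 * S

    # macula near the fundus center, optic disc ~2-2.5 DD nasal of it
    mx = cx + rng.normal(0, 0.03 * S)
    my = cy + rng.normal(0, 0.03 * S)
    dd = rng.uniform(0.13, 0.17) * S
    side = rng.choice([-1.0, 1.0])
    dx = mx + side * rng.uniform(2.0, 2.5) * dd
    dy = my + rng.normal(0, 0.03 * S)
    max_off = radius - dd / 2 - 2
    dx = float(np.clip(dx, cx - max_off, cx + max_off))
    dy = float(np.clip(dy, cy - 0.3 * S, cy + 0.3 * S))

    disc_box = _ellipse_box(dx, dy, dd, dd, Category.OPTIC_DISC)
    macula_box = _ellipse_box(mx, my, 0.9 * dd, 0.9 * dd, Category.MACULA)

    lo, hi = params.he_count_range
    want_dme = hi >= 1 and rng.random() < params.dme_prevalence
    if want_dme:
        n_he = int(rng.integers(max(lo, 1), hi + 1))
    else:
        n_he = int(rng.integers(lo, hi + 1))

    he_boxes: List[Box] = []
    for k in range(n_he):
        w = rng.uniform(*params.he_size_range)
        h = rng.uniform(*params.he_size_range)
        half_diag = math.hypot(w, h) / 2.0
        inside = want_dme and k == 0
        for _ in range(200):
            if inside:
                # nearest box point within 0.85 DD of the macula center
                r = 0.85 * dd * math.sqrt(rng.random())
                theta = rng.uniform(0, 2 * math.pi)
                hx, hy = mx + r * math.cos(theta), my + r * math.sin(theta)
            else:
                hx = rng.uniform(cx - radius, cx + radius)
                hy = rng.uniform(cy - radius, cy + radius)
            if math.hypot(hx - cx, hy - cy) > radius - half_diag - 2:
                continue
            # keep lesions off the bright disc
            if math.hypot(hx - dx, hy - dy) < dd / 2 + half_diag + 2:
                continue
            dist_macula = math.hypot(hx - mx, hy - my)
            if inside:
                break
            if want_dme:
                # extra lesions of a DME scene: anywhere outside the margin band
                if dist_macula - half_diag > 1.15 * dd or dist_macula + half_diag < 0.85 * dd:
                    break
            elif dist_macula - half_diag > 1.15 * dd:
                break
        else:
            raise ValueError("infeasible lesion placement; image too small for requested geometry")
        he_boxes.append(_ellipse_box(hx, hy, w, h, Category.HE))

    truth = SceneTruth(
        image_id=image_id,
        disc_box=disc_box,
        macula_box=macula_box,
        he_boxes=he_boxes,
        fundus_center=Point(cx, cy),
        fundus_radius=radius,
    )
    truth.dme_label = dme_rule(truth.he_boxes, truth.disc_box, truth.macula_box)
    return truth


def _soft_disk(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
               rx: float, ry: float, edge: float = 1.2) -> np.ndarray:
    """Anti-aliased ellipse membership in [0, 1]."""
    d = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    return np.clip((1.0 - d) * (min(rx, ry) / edge), 0.0, 1.0)


def render_scene(
    truth: SceneTruth, params: GeneratorParams, rng: np.random.Generator
) -> ImageRecord:
    """Render the scene geometry to an 8-bit RGB image."""
    S = params.image_size
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64) + 0.5
    img = np.full((S, S, 3), 8.0)

    fc = truth.fundus_center or Point(S / 2, S / 2)
    radius = truth.fundus_radius or 0.47 * S
    fundus = _soft_disk(xx, yy, fc.x, fc.y, radius, radius)
    # radial shading: slightly darker toward the rim
    rr = np.sqrt((xx - fc.x) ** 2 + (yy - fc.y) ** 2) / radius
    shade = 1.0 - 0.25 * np.clip(rr, 0, 1) ** 2
    for c, base in enumerate((175.0, 82.0, 36.0)):
        img[:, :, c] = img[:, :, c] * (1 - fundus) + base * shade * fundus

    m = truth.macula_box
    msx, msy = m.width / 2, m.height / 2
    mc = m.center
    mac = np.exp(-(((xx - mc.x) / msx) ** 2 + ((yy - mc.y) / msy) ** 2))
    for c, target in enumerate((110.0, 46.0, 18.0)):
        img[:, :, c] = img[:, :, c] * (1 - 0.8 * mac) + target * 0.8 * mac

    d = truth.disc_box
    dc = d.center
    disc = _soft_disk(xx, yy, dc.x, dc.y, d.width / 2, d.height / 2)
    for c, target in enumerate((238.0, 214.0, 160.0)):
        img[:, :, c] = img[:, :, c] * (1 - disc) + target * disc

    for he in truth.he_boxes:
        hc = he.center
        blob = _soft_disk(xx, yy, hc.x, hc.y, he.width / 2, he.height / 2)
        for c, target in enumerate((252.0, 246.0, 190.0)):
            img[:, :, c] = img[:, :, c] * (1 - blob) + target * blob

    if params.background_noise_sd > 0:
        img = img + rng.normal(0, params.background_noise_sd, img.shape)
    return ImageRecord(image_id=truth.image_id, pixels=np.clip(img, 0, 255).astype(np.uint8))


def generate_scene(
    params: GeneratorParams, rng_seed: int, image_id: str = "scene"
) -> Tuple[ImageRecord, SceneTruth]:
    """Sample and render one scene deterministically from ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    truth = sample_scene_truth(params, rng, image_id)
    img = render_scene(truth, params, rng)
    return img, truth


def _jitter_box(b: Box, sd: float, size: int, rng: np.random.Generator) -> Optional[Box]:
    x0, y0, x1, y1 = (v + rng.normal(0, sd) for v in (b.x_min, b.y_min, b.x_max, b.y_max))
    x0, x1 = sorted((x0, x1))
    y0, y1 = sorted((y0, y1))
    x0, y0 = max(0.0, x0), max(0.0, y0)
    x1, y1 = min(float(size), x1), min(float(size), y1)
    if x1 - x0 < 2.0:
        cxm = np.clip((x0 + x1) / 2, 1.0, size - 1.0)
        x0, x1 = cxm - 1.0, cxm + 1.0
    if y1 - y0 < 2.0:
        cym = np.clip((y0 + y1) / 2, 1.0, size - 1.0)
        y0, y1 = cym - 1.0, cym + 1.0
    return Box(x0, y0, x1, y1, category=b.category)


def simulate_annotators(
    truth: SceneTruth,
    params: GeneratorParams,
    n_annotators: int = 3,
    rng_seed: int = 0,
) -> List[AnnotationSet]:
    """Simulate annotators who independently jitter, miss, and invent boxes.

    Each true HE box is dropped with ``annotator_miss_rate``, otherwise its
    corners receive Normal(0, ``annotator_jitter_sd``) noise; spurious boxes
    (count ~ Poisson(``annotator_spurious_rate``)) land anywhere in the fundus.
    Output boxes are re-validated to at least 2x2 px inside the image.
    """
    rng = np.random.default_rng(rng_seed)
    S = params.image_size
    fc = truth.fundus_center or Point(S / 2, S / 2)
    radius = truth.fundus_radius or 0.47 * S
    sets: List[AnnotationSet] = []
    for a in range(n_annotators):
        boxes: List[Box] = []
        for b in truth.he_boxes:
            if rng.random() < params.annotator_miss_rate:
                continue
            jb = _jitter_box(b, params.annotator_jitter_sd, S, rng)
            if jb is not None:
                boxes.append(jb)
        for _ in range(rng.poisson(params.annotator_spurious_rate)):
            w = rng.uniform(*params.he_size_range)
            h = rng.uniform(*params.he_size_range)
            r = 0.8 * radius * math.sqrt(rng.random())
            theta = rng.uniform(0, 2 * math.pi)
            cxp, cyp = fc.x + r * math.cos(theta), fc.y + r * math.sin(theta)
            sb = _jitter_box(
                _ellipse_box(cxp, cyp, w, h, Category.HE), 0.0, S, rng
            )
            if sb is not None:
                boxes.append(sb)
        sets.append(
            AnnotationSet(image_id=truth.image_id, annotator_id=f"annotator_{a + 1}", boxes=boxes)
        )
    return sets


def _assign_patients(n_images: int, rng: np.random.Generator) -> List[str]:
    """Group images into synthetic patients owning 1-4 images each; roughly
    half of the patients contribute a single image."""
    owners: List[str] = []
    patient = 0
    while len(owners) < n_images:
        k = int(rng.choice([1, 2, 3, 4], p=[0.55, 0.20, 0.15, 0.10]))
        owners.extend([f"patient_{patient:05d}"] * min(k, n_images - len(owners)))
        patient += 1
    return owners


def generate_dataset(
    n_images: int,
    params: GeneratorParams,
    split_fractions: Sequence[float] = (0.7, 0.15, 0.15),
    rng_seed: int = 0,
    out_dir: Optional[str] = None,
    split_names: Sequence[str] = ("train", "val", "test"),
    write_images: bool = True,
) -> Dict:
    """Generate a full on-disk dataset with a patient-level split.

    Writes PNG images, three annotator JSON files and a consensus JSON per
    image, a truth/label CSV, and a manifest recording the split, patient
    ownership, parameters and seed.  Returns the manifest dict.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(split_fractions) != len(split_names):
        raise ValueError("one name per split fraction required")
    if n_images < len(split_fractions):
        raise ValueError("need at least one image per split")

    ss = np.random.SeedSequence(rng_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    owners = _assign_patients(n_images, rng)
    patients = sorted(set(owners))
    order = rng.permutation(len(patients))

    # allocate whole patients to splits by cumulative image fractions
    split_of_patient: Dict[str, str] = {}
    targets = np.cumsum(np.asarray(split_fractions)) * n_images
    images_per_patient = {p: owners.count(p) for p in patients}
    acc, s_idx = 0, 0
    for pi in order:
        p = patients[pi]
        split_of_patient[p] = split_names[s_idx]
        acc += images_per_patient[p]
        while s_idx < len(split_names) - 1 and acc >= targets[s_idx]:
            s_idx += 1

    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        (root / "images").mkdir(parents=True, exist_ok=True)
        for sub in ("annotations/annotator_1", "annotations/annotator_2",
                    "annotations/annotator_3", "annotations/consensus"):
            (root / sub).mkdir(parents=True, exist_ok=True)

    scene_seeds = ss.spawn(n_images)
    records = []
    labels: Dict[str, int] = {}
    truths: Dict[str, SceneTruth] = {}
    consensus_sets: Dict[str, AnnotationSet] = {}
    for i in range(n_images):
        image_id = f"im_{i:05d}"
        child = np.random.default_rng(scene_seeds[i])
        truth = sample_scene_truth(params, child, image_id)
        ann = simulate_annotators(
            truth, params, rng_seed=int(child.integers(0, 2**31 - 1))
        )
        gt = consensus_gt(ann)
        labels[image_id] = truth.dme_label
        truths[image_id] = truth
        consensus_sets[image_id] = gt
        if root is not None:
            if write_images:
                img = render_scene(truth, params, child)
                save_image(img, str(root / "images" / f"{image_id}.png"))
            for k, a in enumerate(ann, start=1):
                ffio.write_annotation_set(
                    a, root / "annotations" / f"annotator_{k}" / f"{image_id}.json"
                )
            ffio.write_annotation_set(
                gt, root / "annotations" / "consensus" / f"{image_id}.json"
            )
        records.append(
            {
                "image_id": image_id,
                "patient_id": owners[i],
                "split": split_of_patient[owners[i]],
                "dme_label": truth.dme_label,
                "n_he": len(truth.he_boxes),
                "disc_box": ffio.box_to_record(truth.disc_box),
                "macula_box": ffio.box_to_record(truth.macula_box),
                "he_boxes": [ffio.box_to_record(b) for b in truth.he_boxes],
            }
        )

    manifest = {
        "n_images": n_images,
        "rng_seed": rng_seed,
        "params": asdict(params),
        "split_fractions": list(split_fractions),
        "split_names": list(split_names),
        "images": records,
    }
    if root is not None:
        ffio.write_labels_csv(labels, root / "labels.csv")
        (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["_truths"] = truths
    manifest["_consensus"] = consensus_sets
    return manifest
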