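"""Joint training of the fusion model with the weighted two-term loss.

Each minibatch minimises ``omega_ob * E_ob + omega_cl * E_cl`` where the
detector term is averaged over images in the batch and the classification
focal term is averaged over the batch as well.  Horizontal/vertical flip
augmentation is applied per sample, and every source of randomness (shuffle,
flips, dropout) derives from the config seed, so a CPU run is reproducible
to float tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..geometry import Box
from .anchors import assign_targets
from .losses import (
    FocalParams,
    LossBreakdown,
    LossWeights,
    detector_loss,
    focal_loss_tensor,
    detector_loss_tensor,
)
from .model import FusionConfig, FusionModel, _normalize
from .optim import AdamW

__all__ = ["Sample", "train_fusion", "train_single_detector", "evaluate_losses"]


@dataclass
class Sample:
    """One training example: image, ground-truth boxes, image-level label."""

    image: np.ndarray  # HxWx3 uint8
    boxes: List[Box] = field(default_factory=list)
    label: int = 0
    image_id: str = ""


def _flip_sample(s: Sample, do_h: bool, do_v: bool) -> Sample:
    if not (do_h or do_v):
        return s
    img = s.image
    h, w = img.shape[:2]
    boxes = s.boxes
    if do_h:
        img = img[:, ::-1]
        boxes = [Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max, b.score, b.category)
                 for b in boxes]
    if do_v:
        img = img[::-1, :]
        boxes = [Box(b.x_min, h - b.y_max, b.x_max, h - b.y_min, b.score, b.category)
                 for b in boxes]
    return Sample(image=np.ascontiguousarray(img), boxes=boxes, label=s.label,
                  image_id=s.image_id)


def _batch_targets(model: FusionModel, samples: Sequence[Sample]):
    cfg = model.config
    cat_index = {c: i for i, c in enumerate(cfg.det_categories)}
    cls_ts, reg_ts, states = [], [], []
    for s in samples:
        classes = [cat_index[b.category] for b in s.boxes]
        c, r, st = assign_targets(model.anchors, s.boxes, classes, cfg.num_det_classes)
        cls_ts.append(c)
        reg_ts.append(r)
        states.append(st)
    return np.stack(cls_ts), np.stack(reg_ts), np.stack(states)


def train_step(
    model: FusionModel,
    samples: Sequence[Sample],
    optimizer: AdamW,
    omega_ob: float,
    omega_cl: float,
    fp: FocalParams,
) -> LossBreakdown:
    """One gradient step; weights are raw floats so ablations (a zero weight)
    are possible even though the public LossWeights type is strictly positive."""
    batch = _normalize(np.stack([s.image for s in samples]))
    det_cls, det_reg, dme_logit = model.forward_tensors(batch)

    has_det = hasattr(model, "det_head")
    has_cls = hasattr(model, "cls_head")

    e_ob_t = None
    if has_det:
        cls_t, reg_t, states = _batch_targets(model, samples)
        e_ob_t = detector_loss_tensor(det_cls, det_reg, cls_t, reg_t, states, fp)
    e_cl_t = None
    if has_cls:
        labels = np.asarray([[s.label] for s in samples], dtype=float)
        e_cl_t = focal_loss_tensor(
            dme_logit, labels, np.ones_like(labels), fp, normalizer=float(len(samples))
        )

    total = None
    if e_ob_t is not None and omega_ob != 0.0:
        total = e_ob_t * omega_ob
    if e_cl_t is not None and omega_cl != 0.0:
        total = e_cl_t * omega_cl if total is None else total + e_cl_t * omega_cl

    optimizer.zero_grad()
    if total is not None:
        total.backward()
        optimizer.step()

    e_ob = float(e_ob_t.data) if e_ob_t is not None else 0.0
    e_cl = float(e_cl_t.data) if e_cl_t is not None else 0.0
    return LossBreakdown(e_ob=e_ob, e_cl=e_cl, e_total=omega_ob * e_ob + omega_cl * e_cl)


def evaluate_losses(
    model: FusionModel, dataset: Sequence[Sample], fp: FocalParams,
    batch_size: int = 16,
) -> Tuple[float, float]:
    """Mean detector and classification losses without gradient bookkeeping."""
    was_training = model.training
    model.eval()
    e_obs, e_cls = [], []
    cfg = model.config
    cat_index = {c: i for i, c in enumerate(cfg.det_categories)}
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start: start + batch_size]
        batch = _normalize(np.stack([s.image for s in chunk]))
        det_cls, det_reg, dme_logit = model.forward_tensors(batch)
        if hasattr(model, "det_head"):
            probs = 1.0 / (1.0 + np.exp(-det_cls.data))
            for i, s in enumerate(chunk):
                classes = [cat_index[b.category] for b in s.boxes]
                e_obs.append(
                    detector_loss(probs[i], det_reg.data[i], s.boxes, model.anchors,
                                  classes, fp)
                )
        if hasattr(model, "cls_head"):
            from .losses import focal_term

            for i, s in enumerate(chunk):
                p = float(1.0 / (1.0 + np.exp(-dme_logit.data[i, 0])))
                e_cls.append(focal_term(p, s.label, fp))
    if was_training:
        model.train()
    return (float(np.mean(e_obs)) if e_obs else 0.0,
            float(np.mean(e_cls)) if e_cls else 0.0)


def train_fusion(
    model: FusionModel,
    dataset: Sequence[Sample],
    w: LossWeights = LossWeights(),
    fp: FocalParams = FocalParams(),
    config: Optional[FusionConfig] = None,
    epochs: int = 20,
    val_dataset: Optional[Sequence[Sample]] = None,
    augment: bool = True,
    verbose: bool = False,
) -> Tuple[FusionModel, List[Dict]]:
    """Jointly minimise the combined loss; returns the model and a per-epoch
    history of training (and optional validation) loss terms."""
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = config or model.config
    rng = np.random.default_rng(cfg.rng_seed + 1)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history: List[Dict] = []
    model.train()
    n = len(dataset)
    for epoch in range(epochs):
        # half-cosine decay of the learning rate over the schedule
        opt.lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, epochs)))
        order = rng.permutation(n)
        ep_ob, ep_cl, n_batches = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            samples = [dataset[i] for i in idx]
            if augment:
                samples = [
                    _flip_sample(s, rng.random() < 0.5, rng.random() < 0.5)
                    for s in samples
                ]
            br = train_step(model, samples, opt, w.omega_ob, w.omega_cl, fp)
            ep_ob += br.e_ob
            ep_cl += br.e_cl
            n_batches += 1
        entry = {
            "epoch": epoch,
            "e_ob": ep_ob / n_batches,
            "e_cl": ep_cl / n_batches,
            "e_total": w.omega_ob * ep_ob / n_batches + w.omega_cl * ep_cl / n_batches,
        }
        if val_dataset:
            v_ob, v_cl = evaluate_losses(model, val_dataset, fp, cfg.batch_size)
            entry.update(
                val_e_ob=v_ob, val_e_cl=v_cl,
                val_e_total=w.omega_ob * v_ob + w.omega_cl * v_cl,
            )
        history.append(entry)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4g}" for k, v in entry.items()
                                                  if k != "epoch"))
    return model, history


def train_single_detector(
    model: FusionModel,
    dataset: Sequence[Sample],
    fp: FocalParams = FocalParams(),
    config: Optional[FusionConfig] = None,
    epochs: int = 20,
    augment: bool = True,
) -> Tuple[FusionModel, List[Dict]]:
    """Train a detection-only model (dual-model half or landmark detector)."""
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = config or model.config
    rng = np.random.default_rng(cfg.rng_seed + 1)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history: List[Dict] = []
    model.train()
    n = len(dataset)
    for epoch in range(epochs):
        opt.lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, epochs)))
        order = rng.permutation(n)
        ep_ob, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            samples = [dataset[i] for i in order[start: start + cfg.batch_size]]
            if augment:
                samples = [
                    _flip_sample(s, rng.random() < 0.5, rng.random() < 0.5)
                    for s in samples
                ]
            br = train_step(model, samples, opt, 1.0, 0.0, fp)
            ep_ob += br.e_ob
            n_batches += 1
        history.append({"epoch": epoch, "e_ob": ep_ob / n_batches})
    return model, history
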