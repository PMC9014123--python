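"""The shared-backbone fusion architecture.

One convolutional feature extractor feeds two heads: a bi-directional
feature-pyramid detection path (lesion boxes) and a three-layer
classification path — exactly one convolution, one global average pooling,
and one fully connected layer with dropout — producing the DME probability.
Both paths share every backbone parameter, so the joint model is strictly
smaller than a matched pair of single-task models.

The backbone is a configurable width/depth stack, not a replica of any named
full-scale network: the contract here is the topology (shared trunk, pyramid
detection head, conv-GAP-FC classification head) and the fused loss, at a
size a CPU can train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..geometry import Box, Category
from ..preprocessing import ImageRecord
from .anchors import AnchorGrid, build_anchors, decode_boxes, nms
from .autograd import Tensor, concat
from .layers import Conv2d, Linear, Module, Scalar
from .losses import ClassificationOutput

__all__ = [
    "FusionConfig",
    "FusionModel",
    "SingleTaskDetector",
    "SingleTaskClassifier",
    "build_fusion",
    "build_single_detector",
    "build_single_classifier",
    "forward_fusion",
    "save_checkpoint",
    "load_checkpoint",
]

# image normalisation applied before every forward pass
PIXEL_MEAN = 127.5
PIXEL_SCALE = 64.0


@dataclass
class FusionConfig:
    """Architecture and optimisation settings.

    The optimisation defaults (learning rate 1e-4, dropout 0.2, batch 16,
    weight decay 0.01, AdamW) are the full-scale settings; :meth:`tiny`
    returns the desk-scale instantiation used throughout the tests, with a
    128 px input, a narrow backbone and a larger learning rate suited to the
    short schedules small models train under.
    """

    input_size: int = 640
    base_width: int = 32
    pyramid_levels: Tuple[int, ...] = (3, 4)
    num_det_classes: int = 1
    det_categories: Tuple[str, ...] = (Category.HE,)
    anchor_base_scale: float = 1.0
    dropout_rate: float = 0.2
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 16
    score_threshold: float = 0.3
    nms_iou: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        stride = 2 ** max(self.pyramid_levels)
        if self.input_size % stride != 0:
            raise ValueError(
                f"input_size {self.input_size} incompatible with pyramid levels "
                f"{self.pyramid_levels} (must be divisible by {stride})"
            )
        if sorted(self.pyramid_levels) != list(self.pyramid_levels) or len(self.pyramid_levels) < 1:
            raise ValueError("pyramid_levels must be ascending and non-empty")
        if len(self.det_categories) != self.num_det_classes:
            raise ValueError("one category name per detection class required")

    @classmethod
    def tiny(cls, rng_seed: int = 0, **overrides) -> "FusionConfig":
        kw = dict(
            input_size=128,
            base_width=24,
            batch_size=4,
            learning_rate=1e-3,
            rng_seed=rng_seed,
        )
        kw.update(overrides)
        return cls(**kw)


class Backbone(Module):
    """Stride-2 convolution stack producing features at 1/8 and 1/16 scale."""

    def __init__(self, width: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = width
        self.stem = Conv2d(3, w, 3, rng, stride=2)        # /2
        self.c2 = Conv2d(w, 2 * w, 3, rng, stride=2)      # /4
        self.c3 = Conv2d(2 * w, 4 * w, 3, rng, stride=2)  # /8
        self.c3b = Conv2d(4 * w, 4 * w, 3, rng, stride=1)
        self.c4 = Conv2d(4 * w, 4 * w, 3, rng, stride=2)  # /16
        self.c4b = Conv2d(4 * w, 4 * w, 3, rng, stride=1)
        self.out_channels = 4 * w

    def __call__(self, x: Tensor) -> Dict[int, Tensor]:
        h = self.stem(x).relu()
        h = self.c2(h).relu()
        p3 = self.c3b(self.c3(h).relu()).relu()
        p4 = self.c4b(self.c4(p3).relu()).relu()
        return {3: p3, 4: p4}


class BiFPN(Module):
    """One bidirectional fusion cell over two pyramid levels.

    Features are projected to a common width, merged top-down and then
    bottom-up with learnable non-negative scalar weights (fast-normalised),
    each merge followed by a 3x3 convolution.
    """

    def __init__(self, in_channels: int, fpn_channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.lat3 = Conv2d(in_channels, fpn_channels, 1, rng)
        self.lat4 = Conv2d(in_channels, fpn_channels, 1, rng)
        self.conv_td = Conv2d(fpn_channels, fpn_channels, 3, rng)
        self.conv_bu = Conv2d(fpn_channels, fpn_channels, 3, rng)
        self.w_td = [Scalar(1.0), Scalar(1.0)]
        self.w_bu = [Scalar(1.0), Scalar(1.0)]
        self.out_channels = fpn_channels

    @staticmethod
    def _fuse(a: Tensor, b: Tensor, weights: List[Scalar]) -> Tensor:
        wa, wb = weights[0](), weights[1]()
        denom = wa + wb + 1e-4
        return (a * wa + b * wb) * denom.pow(-1.0)

    def __call__(self, feats: Dict[int, Tensor]) -> Dict[int, Tensor]:
        l3, l4 = self.lat3(feats[3]), self.lat4(feats[4])
        p3 = self.conv_td(self._fuse(l3, l4.upsample2(), self.w_td).relu())
        p4 = self.conv_bu(self._fuse(l4, p3.avg_pool2(), self.w_bu).relu())
        return {3: p3, 4: p4}


class DetectionHead(Module):
    """Shared-weight head: a 3x3 conv trunk, then class and box 3x3 convs.

    The class conv bias starts at the background prior logit (-log(99)) so
    early training is not swamped by the background focal term.
    """

    def __init__(self, channels: int, n_anchors: int, n_classes: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.trunk = Conv2d(channels, channels, 3, rng)
        prior_logit = -float(np.log((1 - 0.01) / 0.01))
        self.cls = Conv2d(channels, n_anchors * n_classes, 3, rng, bias_init=prior_logit)
        self.reg = Conv2d(channels, n_anchors * 4, 3, rng)
        self.n_anchors = n_anchors
        self.n_classes = n_classes

    def __call__(self, feats: Dict[int, Tensor]) -> Tuple[Tensor, Tensor]:
        cls_out, reg_out = [], []
        for level in sorted(feats):
            h = self.trunk(feats[level]).relu()
            c, r = self.cls(h), self.reg(h)
            n, _, hh, ww = c.data.shape
            # (N, A*K, H, W) -> (N, H, W, A, K) -> (N, H*W*A, K)
            c = c.reshape(n, self.n_anchors, self.n_classes, hh, ww)
            c = c.transpose((0, 3, 4, 1, 2)).reshape(n, hh * ww * self.n_anchors, self.n_classes)
            r = r.reshape(n, self.n_anchors, 4, hh, ww)
            r = r.transpose((0, 3, 4, 1, 2)).reshape(n, hh * ww * self.n_anchors, 4)
            cls_out.append(c)
            reg_out.append(r)
        return concat(cls_out, axis=1), concat(reg_out, axis=1)


class ClassificationHead(Module):
    """Exactly one convolution, one global average pooling, one FC layer."""

    def __init__(self, channels: int, dropout_rate: float, rng: np.random.Generator,
                 width: int = 0) -> None:
        super().__init__()
        width = width or 2 * channels
        self.conv = Conv2d(channels, width, 3, rng)
        self.fc = Linear(width, 1, rng)
        self.dropout_rate = dropout_rate
        self._rng = rng

    def __call__(self, feat: Tensor) -> Tensor:
        h = self.conv(feat).relu()
        pooled = h.mean(axis=(2, 3))  # global average pooling -> (N, C)
        pooled = pooled.dropout(self.dropout_rate, self._rng, self.training)
        return self.fc(pooled)  # logits (N, 1)


def _normalize(img: np.ndarray) -> np.ndarray:
    x = (img.astype(np.float64) - PIXEL_MEAN) / PIXEL_SCALE
    return x.transpose(2, 0, 1)[None] if x.ndim == 3 else x.transpose(0, 3, 1, 2)


class FusionModel(Module):
    """Shared backbone + BiFPN detection path + conv/GAP/FC classification path."""

    def __init__(self, config: FusionConfig) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        w = config.base_width
        self.backbone = Backbone(w, rng)
        self.fpn = BiFPN(self.backbone.out_channels, 2 * w, rng)
        self.det_head = DetectionHead(2 * w, len(build_anchor_scales()), config.num_det_classes, rng)
        self.cls_head = ClassificationHead(self.backbone.out_channels, config.dropout_rate, rng)
        self.anchors: AnchorGrid = build_anchors(
            config.input_size, config.pyramid_levels, config.anchor_base_scale
        )

    # ---- forward passes -------------------------------------------------

    def forward_tensors(self, batch: np.ndarray) -> Tuple[Tensor, Tensor, Tensor]:
        """(cls_logits (N,A,K), reg (N,A,4), dme_logit (N,1)) on a float batch."""
        x = Tensor(batch)
        feats = self.backbone(x)
        pyramids = self.fpn(feats)
        det_cls, det_reg = self.det_head(pyramids)
        dme_logit = self.cls_head(feats[4])
        return det_cls, det_reg, dme_logit

    def predict(self, img: ImageRecord) -> Tuple[List[Box], ClassificationOutput]:
        """Inference: thresholded + NMS detections and the DME probability."""
        if img.pixels.shape[:2] != (self.config.input_size, self.config.input_size):
            raise ValueError(
                f"expected {self.config.input_size}x{self.config.input_size} input, "
                f"got {img.pixels.shape[:2]}"
            )
        was_training = self.training
        self.eval()
        det_cls, det_reg, dme_logit = self.forward_tensors(_normalize(img.pixels))
        if was_training:
            self.train()
        probs = 1.0 / (1.0 + np.exp(-det_cls.data[0]))  # (A, K)
        offsets = det_reg.data[0]
        boxes = decode_boxes(self.anchors, offsets, self.config.input_size)
        detections: List[Box] = []
        for k in range(self.config.num_det_classes):
            sel = np.flatnonzero(probs[:, k] >= self.config.score_threshold)
            if sel.size == 0:
                continue
            kept = nms(boxes[sel], probs[sel, k], self.config.nms_iou)
            for i in (sel[j] for j in kept):
                x0, y0, x1, y1 = boxes[i]
                if x1 - x0 < 1e-3 or y1 - y0 < 1e-3:
                    continue
                detections.append(
                    Box(x0, y0, x1, y1, score=float(probs[i, k]),
                        category=self.config.det_categories[k])
                )
        p = float(1.0 / (1.0 + np.exp(-dme_logit.data[0, 0])))
        return detections, ClassificationOutput(p=p)

    def detect(self, img: ImageRecord) -> List[Box]:
        """Detection-only interface (satisfies the landmark Detector protocol)."""
        return self.predict(img)[0]

    def classification_parameters(self) -> List[Tensor]:
        return self.cls_head.parameters()

    def detection_parameters(self) -> List[Tensor]:
        return self.fpn.parameters() + self.det_head.parameters()

    def backbone_parameters(self) -> List[Tensor]:
        return self.backbone.parameters()


def build_anchor_scales() -> Tuple[float, ...]:
    from .anchors import SCALES

    return tuple(SCALES)


class SingleTaskDetector(FusionModel):
    """Detection-only model: same backbone/FPN/detection head, no classifier.

    Used as one half of the dual-model baseline and as the anatomical
    landmark detector (with disc/macula categories).
    """

    def __init__(self, config: FusionConfig) -> None:
        super().__init__(config)
        del self.cls_head

    def forward_tensors(self, batch: np.ndarray):
        x = Tensor(batch)
        feats = self.backbone(x)
        det_cls, det_reg = self.det_head(self.fpn(feats))
        return det_cls, det_reg, Tensor(np.zeros((batch.shape[0], 1)))


class SingleTaskClassifier(FusionModel):
    """Classification-only model: same backbone and classification head."""

    def __init__(self, config: FusionConfig) -> None:
        super().__init__(config)
        del self.fpn
        del self.det_head

    def forward_tensors(self, batch: np.ndarray):
        x = Tensor(batch)
        feats = self.backbone(x)
        dme_logit = self.cls_head(feats[4])
        n = batch.shape[0]
        a = len(self.anchors)
        return (
            Tensor(np.zeros((n, a, self.config.num_det_classes))),
            Tensor(np.zeros((n, a, 4))),
            dme_logit,
        )

    def predict(self, img: ImageRecord):
        if img.pixels.shape[:2] != (self.config.input_size, self.config.input_size):
            raise ValueError("wrong input size")
        was_training = self.training
        self.eval()
        _, _, dme_logit = self.forward_tensors(_normalize(img.pixels))
        if was_training:
            self.train()
        p = float(1.0 / (1.0 + np.exp(-dme_logit.data[0, 0])))
        return [], ClassificationOutput(p=p)


def build_fusion(config: FusionConfig) -> FusionModel:
    """Construct the fusion model; identical seeds give identical parameters."""
    return FusionModel(config)


def build_single_detector(config: FusionConfig) -> SingleTaskDetector:
    return SingleTaskDetector(config)


def build_single_classifier(config: FusionConfig) -> SingleTaskClassifier:
    return SingleTaskClassifier(config)


def forward_fusion(model: FusionModel, img: ImageRecord) -> Tuple[List[Box], ClassificationOutput]:
    """Single-backbone-evaluation inference on one image."""
    return model.predict(img)


def save_checkpoint(model: FusionModel, path: str, extra: Optional[Dict] = None) -> None:
    """Parameters as an .npz plus a JSON sidecar with the config and seeds."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {"config": asdict(model.config), "kind": type(model).__name__}
    if extra:
        sidecar.update(extra)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str) -> FusionModel:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["pyramid_levels"] = tuple(cfg_dict["pyramid_levels"])
    cfg_dict["det_categories"] = tuple(cfg_dict["det_categories"])
    config = FusionConfig(**cfg_dict)
    kind = sidecar.get("kind", "FusionModel")
    model = {
        "FusionModel": FusionModel,
        "SingleTaskDetector": SingleTaskDetector,
        "SingleTaskClassifier": SingleTaskClassifier,
    }[kind](config)
    data = np.load(path if str(path).endswith(".npz") else str(path))
    model.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
    return model
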