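"""The shared-backbone model: construction, sharing, gradients, inference."""

import numpy as np
import pytest

from fundusfusion.fusion import (
    FocalParams,
    FusionConfig,
    build_fusion,
    build_single_classifier,
    build_single_detector,
    load_checkpoint,
    save_checkpoint,
)
from fundusfusion.fusion.anchors import build_anchors, decode_boxes, nms
from fundusfusion.fusion.autograd import Tensor
from fundusfusion.fusion.optim import AdamW
from fundusfusion.fusion.train import Sample, train_step
from fundusfusion.preprocessing import ImageRecord


def small_config(seed=0, **kw):
    kw.setdefault("input_size", 64)
    kw.setdefault("base_width", 8)
    return FusionConfig.tiny(rng_seed=seed, **kw)


def random_image(rng, size=64) -> ImageRecord:
    return ImageRecord("r", rng.integers(0, 255, (size, size, 3)).astype(np.uint8))


class TestAutogradEngine:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        X = Tensor(rng.normal(size=(2, 3, 9, 9)), requires_grad=True)
        W = Tensor(rng.normal(size=(4, 3, 3, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)

        def f():
            h = X.conv2d(W, b, stride=2, padding=1).relu()
            h = h.upsample2().avg_pool2().sigmoid()
            return (h * h).mean()

        f().backward()
        for t in (X, W, b):
            grad = t.grad.copy()
            num = np.zeros_like(t.data)
            eps = 1e-6
            it = np.nditer(t.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                t.data[i] += eps
                lp = float(f().data)
                t.data[i] -= 2 * eps
                lm = float(f().data)
                t.data[i] += eps
                num[i] = (lp - lm) / (2 * eps)
            assert np.max(np.abs(num - grad)) < 1e-6 * max(1.0, np.max(np.abs(num)))


class TestAnchors:
    def test_decode_inverts_encoding(self, rng):
        from fundusfusion.fusion.anchors import assign_targets
        from fundusfusion.geometry import Box

        grid = build_anchors(64, (3, 4))
        gt = [Box(10.0, 12.0, 26.0, 30.0, category="HE")]
        _, reg_t, state = assign_targets(grid, gt, [0], 1)
        pos = np.flatnonzero(state == 1)
        decoded = decode_boxes(grid, reg_t)
        for i in pos:
            assert np.allclose(decoded[i], [10, 12, 26, 30], atol=1e-9)

    def test_nms_suppresses_overlaps(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40]], float)
        scores = np.array([0.9, 0.8, 0.7])
        assert nms(boxes, scores, 0.5) == [0, 2]


class TestModelConstruction:
    def test_fusion_smaller_than_dual(self):
        cfg = small_config()
        fusion = build_fusion(cfg)
        dual = build_single_detector(cfg).n_parameters() + \
            build_single_classifier(cfg).n_parameters()
        assert fusion.n_parameters() < dual

    def test_same_seed_identical_parameters(self):
        a, b = build_fusion(small_config(3)), build_fusion(small_config(3))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_forward_on_zero_image_is_well_formed(self):
        m = build_fusion(small_config())
        img = ImageRecord("z", np.zeros((64, 64, 3), dtype=np.uint8))
        dets, cls = m.predict(img)
        assert 0.0 <= cls.p <= 1.0
        for d in dets:
            assert d.x_min < d.x_max and d.y_min < d.y_max

    def test_eval_mode_deterministic(self, rng):
        m = build_fusion(small_config())
        img = random_image(rng)
        d1, c1 = m.predict(img)
        d2, c2 = m.predict(img)
        assert c1.p == c2.p and len(d1) == len(d2)

    def test_wrong_input_size_rejected(self, rng):
        m = build_fusion(small_config())
        with pytest.raises(ValueError):
            m.predict(random_image(rng, size=128))

    def test_incompatible_pyramid_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(input_size=100, pyramid_levels=(3, 4))


class TestGradientRouting:
    def _samples(self, rng, n=2):
        from fundusfusion.geometry import Box

        out = []
        for _ in range(n):
            img = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
            out.append(Sample(image=img, boxes=[Box(10, 10, 22, 22, category="HE")],
                              label=int(rng.integers(0, 2))))
        return out

    def test_zero_classification_weight_freezes_classifier_head(self, rng):
        m = build_fusion(small_config())
        samples = self._samples(rng)
        cls_before = [p.data.copy() for p in m.classification_parameters()]
        det_before = [p.data.copy() for p in m.detection_parameters()]
        opt = AdamW(m.parameters(), lr=1e-3)
        train_step(m, samples, opt, omega_ob=1.0, omega_cl=0.0, fp=FocalParams())
        assert all(
            np.array_equal(a, p.data)
            for a, p in zip(cls_before, m.classification_parameters())
        )
        assert any(
            not np.array_equal(a, p.data)
            for a, p in zip(det_before, m.detection_parameters())
        )

    def test_zero_detection_weight_freezes_detection_path(self, rng):
        m = build_fusion(small_config())
        samples = self._samples(rng)
        det_before = [p.data.copy() for p in m.detection_parameters()]
        backbone_before = [p.data.copy() for p in m.backbone_parameters()]
        opt = AdamW(m.parameters(), lr=1e-3)
        train_step(m, samples, opt, omega_ob=0.0, omega_cl=1.0, fp=FocalParams())
        assert all(
            np.array_equal(a, p.data)
            for a, p in zip(det_before, m.detection_parameters())
        )
        # the shared backbone moves under the classification gradient alone
        assert any(
            not np.array_equal(a, p.data)
            for a, p in zip(backbone_before, m.backbone_parameters())
        )

    def test_training_step_reproducible(self, rng):
        results = []
        for _ in range(2):
            m = build_fusion(small_config(5))
            r = np.random.default_rng(99)
            samples = self._samples(r)
            opt = AdamW(m.parameters(), lr=1e-3)
            br = train_step(m, samples, opt, 0.5, 100.0, FocalParams())
            results.append((br.e_ob, br.e_cl))
        assert results[0] == results[1]


class TestCheckpointing:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        m = build_fusion(small_config(7))
        img = random_image(rng)
        dets, cls = m.predict(img)
        path = str(tmp_path / "model.npz")
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        dets2, cls2 = m2.predict(img)
        assert cls.p == cls2.p
        assert len(dets) == len(dets2)
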