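"""Box geometry, GIoU, detection losses, and the toy dense detector."""

import numpy as np
import pytest

from dynacolor.toy_detector import (Box, Detection, GridTargets, ToyDetector,
                                    _giou_and_grad, assign_targets,
                                    detection_loss, giou, iou, nms,
                                    toy_detect)


class TestIoU:
    def test_hand_computed_values(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 1), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            giou((0, 0, 1, 1), (2, 2, 1, 3))

    def test_symmetry_and_translation_invariance(self, rng):
        for _ in range(100):
            a = np.sort(rng.uniform(0, 50, 4).reshape(2, 2), axis=0).T.ravel()
            b = np.sort(rng.uniform(0, 50, 4).reshape(2, 2), axis=0).T.ravel()
            a = [a[0], a[2], a[1] + 1, a[3] + 1]
            b = [b[0], b[2], b[1] + 1, b[3] + 1]
            t = rng.uniform(-20, 20, 2)
            shift = np.array([t[0], t[1], t[0], t[1]])
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert giou(a, b) == pytest.approx(giou(b, a))
            assert giou(np.array(a) + shift, np.array(b) + shift) == \
                pytest.approx(giou(a, b), abs=1e-9)
            assert giou(a, b) <= iou(a, b) + 1e-12


class TestGIoU:
    def test_hand_computed_values(self):
        assert giou((0, 0, 1, 1), (0, 0, 1, 1)) == 1.0
        # touching boxes: hull equals union, IoU 0
        assert giou((0, 0, 1, 1), (1, 0, 2, 1)) == pytest.approx(0.0)
        # far apart: hull 100, union 2 -> -(98/100)
        assert giou((0, 0, 1, 1), (9, 9, 10, 10)) == pytest.approx(-0.98)

    def test_equals_iou_when_hull_equals_union(self):
        # one box inside a larger one that spans the hull
        a, b = (0, 0, 10, 10), (2, 3, 7, 8)
        assert giou(a, b) == pytest.approx(iou(a, b))

    def test_agrees_with_rasterized_counting_oracle(self, rng):
        """Integer-lattice boxes: cell counting gives exact areas."""
        for _ in range(100):
            ax = np.sort(rng.choice(21, 2, replace=False))
            ay = np.sort(rng.choice(21, 2, replace=False))
            bx = np.sort(rng.choice(21, 2, replace=False))
            by = np.sort(rng.choice(21, 2, replace=False))
            a = (ax[0], ay[0], ax[1], ay[1])
            b = (bx[0], by[0], bx[1], by[1])
            grid = np.zeros((21, 21, 2), dtype=bool)
            grid[ay[0]:ay[1], ax[0]:ax[1], 0] = True
            grid[by[0]:by[1], bx[0]:bx[1], 1] = True
            inter = np.sum(grid[..., 0] & grid[..., 1])
            union = np.sum(grid[..., 0] | grid[..., 1])
            ys, xs = np.nonzero(grid.any(axis=-1))
            hull = ((xs.max() - xs.min() + 1) * (ys.max() - ys.min() + 1))
            expected = inter / union - (hull - union) / hull
            assert giou(a, b) == pytest.approx(expected, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        pred = np.array([[3.0, 4.0, 12.0, 15.0],
                         [0.5, 0.5, 5.5, 5.5],
                         [20.0, 20.0, 30.0, 31.0]])
        tgt = np.array([[5.0, 2.0, 14.0, 12.0],
                        [1.0, 1.0, 6.0, 7.0],
                        [0.0, 0.0, 4.0, 4.0]])
        g, grad = _giou_and_grad(pred, tgt)
        eps = 1e-6
        for m in range(pred.shape[0]):
            for k in range(4):
                p = pred.copy()
                p[m, k] += eps
                g2, _ = _giou_and_grad(p, tgt)
                assert (g2[m] - g[m]) / eps == pytest.approx(
                    grad[m, k], abs=1e-5)


class TestTargetsAndLoss:
    STRIDE, BASE = 8, 10.0

    def _raw_for(self, boxes, hg=4, wg=4):
        """Raw grid whose decode exactly reproduces center-anchored boxes."""
        raw = np.full((5, hg, wg), -40.0)   # objectness ~ 0 everywhere
        raw[1:] = 0.0
        for b in boxes:
            cx, cy = b.center
            gx, gy = int(cx // self.STRIDE), int(cy // self.STRIDE)
            raw[0, gy, gx] = 40.0           # objectness ~ 1
            # sigma(0)=0.5 centers the box in the cell; solve for w/h
            raw[3, gy, gx] = np.log((b.x_max - b.x_min) / self.BASE)
            raw[4, gy, gx] = np.log((b.y_max - b.y_min) / self.BASE)
        return raw

    def test_perfect_predictions_have_zero_loss(self):
        # boxes centered on cell centers are exactly representable
        boxes = [Box(8, 8, 16, 16), Box(24, 24, 32, 32)]
        raw = self._raw_for(boxes)
        targets = assign_targets(boxes, 4, 4, self.STRIDE)
        lc, ll = detection_loss(raw, targets, self.STRIDE, self.BASE)
        assert ll == pytest.approx(0.0, abs=1e-9)
        assert lc == pytest.approx(0.0, abs=1e-6)

    def test_no_truth_no_objectness_no_loss(self):
        raw = np.full((5, 4, 4), 0.0)
        raw[0] = -40.0
        targets = assign_targets([], 4, 4, self.STRIDE)
        lc, ll = detection_loss(raw, targets, self.STRIDE, self.BASE)
        assert lc == pytest.approx(0.0, abs=1e-6)
        assert ll == 0.0

    def test_shifted_box_loss_matches_giou_op(self):
        truth = Box(8, 8, 16, 16)
        pred_box = Box(24, 24, 32, 32)   # decoded at the truth's cell
        raw = self._raw_for([truth])
        raw[3, 1, 1] = np.log(8 / self.BASE)
        raw[4, 1, 1] = np.log(8 / self.BASE)
        # move the predicted box by planting the truth's cell prediction
        # at a different size/offset is limited; instead assign a truth
        # far from the decoded box to get a clean cross-check
        targets = assign_targets([truth], 4, 4, self.STRIDE)
        targets.boxes[1, 1] = pred_box.as_array()
        _, ll = detection_loss(raw, targets, self.STRIDE, self.BASE)
        decoded = Box(8, 8, 16, 16)
        assert ll == pytest.approx(1 - giou(decoded, pred_box), abs=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            detection_loss(np.zeros((5, 0, 0)),
                           GridTargets(np.zeros((0, 0)),
                                       np.zeros((0, 0, 4))),
                           self.STRIDE, self.BASE)

    def test_center_collision_prefers_closest_then_smaller(self):
        # both centers in cell (0,0); second is closer to the cell center
        b_far = Box(0, 0, 2, 2)
        b_close = Box(2, 2, 6, 6)
        t = assign_targets([b_far, b_close], 2, 2, 8)
        assert t.n_positive == 1
        assert t.boxes[0, 0] == pytest.approx(b_close.as_array())


class TestDetect:
    def test_zero_weight_model_detects_nothing(self, scene64):
        det = ToyDetector(seed=0)
        for k in det.params:
            det.params[k][:] = 0.0
        assert toy_detect(det, scene64[0], 0.5, 0.5) == []

    def test_single_dominant_cell_yields_one_detection(self, scene64):
        class FixedRaw(ToyDetector):
            def forward(self, images):
                raw = np.full((images.shape[0], 5, 8, 8), -40.0)
                raw[:, 1:] = 0.0
                raw[:, 0, 3, 4] = 3.0       # one confident cell
                return raw, None
        dets = toy_detect(FixedRaw(), scene64[0], 0.5, 0.5)
        assert len(dets) == 1
        cx, cy = dets[0].box.center
        assert (cx, cy) == pytest.approx((4.5 * 8, 3.5 * 8))

    def test_nms_suppresses_duplicates(self):
        d1 = Detection(Box(0, 0, 10, 10), 0.9)
        d2 = Detection(Box(0, 0, 10, 10), 0.8)
        d3 = Detection(Box(40, 40, 50, 50), 0.7)
        kept = nms([d1, d2, d3], iou_threshold=0.5)
        assert kept == [d1, d3]

    def test_detections_sorted_by_confidence(self, clean_detector, scene64):
        dets = clean_detector.detect(scene64[0], confidence_threshold=0.3)
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)

    def test_image_smaller_than_grid_cell_rejected(self):
        with pytest.raises(ValueError):
            toy_detect(ToyDetector(), np.zeros((4, 4, 3)), 0.5, 0.5)
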