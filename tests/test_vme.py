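"""Voting-based model ensemble and test-time augmentation."""

import numpy as np
import pytest

from dynacolor.toy_detector import Box, Detection, iou
from dynacolor.vme import (AUGMENTATIONS, PredictionSet, VMEConfig,
                           tta_predict, vme_fuse, vme_fuse_oracle)


def det(x0, y0, x1, y1, conf=0.9):
    return Detection(Box(x0, y0, x1, y1), conf)


def random_sets(rng, k, max_boxes_per_set=6, frame=100.0):
    sets = []
    for i in range(k):
        n = int(rng.integers(0, max_boxes_per_set + 1))
        dets = []
        for _ in range(n):
            x, y = rng.uniform(0, frame - 20, 2)
            w, h = rng.uniform(4, 20, 2)
            dets.append(det(x, y, x + w, y + h,
                            round(float(rng.uniform(0.05, 1.0)), 4)))
        sets.append(PredictionSet(source=i, detections=dets))
    return sets


class TestFusionRule:
    def test_three_agreeing_boxes_average(self):
        sets = [PredictionSet(0, [det(10, 10, 20, 20, 0.9)]),
                PredictionSet(1, [det(11, 10, 21, 20, 0.6)]),
                PredictionSet(2, [det(10, 11, 20, 21, 0.3)])]
        fused = vme_fuse(sets, VMEConfig(tau=0.6))
        assert len(fused) == 1
        assert fused[0].box.as_array() == pytest.approx(
            [31 / 3, 31 / 3, 61 / 3, 61 / 3])
        assert fused[0].confidence == pytest.approx(0.6)

    def test_lone_box_discarded_with_k3(self):
        sets = [PredictionSet(0, [det(10, 10, 20, 20)]),
                PredictionSet(1, []), PredictionSet(2, [])]
        assert vme_fuse(sets) == []

    def test_two_of_three_survive(self):
        sets = [PredictionSet(0, [det(10, 10, 20, 20)]),
                PredictionSet(1, [det(10, 10, 20, 20, 0.5)]),
                PredictionSet(2, [])]
        assert len(vme_fuse(sets)) == 1

    def test_k1_passes_everything_through(self):
        dets = [det(0, 0, 5, 5, 0.9), det(20, 20, 30, 30, 0.4)]
        fused = vme_fuse([PredictionSet(0, dets)])
        assert fused == sorted(dets, key=lambda d: -d.confidence)

    def test_duplicated_identical_sets_preserve_boxes(self):
        dets = [det(0, 0, 5, 5, 0.8), det(50, 50, 60, 60, 0.6)]
        sets = [PredictionSet(i, list(dets)) for i in range(3)]
        fused = vme_fuse(sets)
        assert len(fused) == 2
        for f, d in zip(fused, dets):
            assert f.box.as_array() == pytest.approx(d.box.as_array())
            assert f.confidence == pytest.approx(d.confidence)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            vme_fuse([])
        with pytest.raises(ValueError):
            vme_fuse([PredictionSet(0, []), PredictionSet(0, [])])

    def test_at_most_one_box_per_source_per_cluster(self):
        # source 1 offers two similar boxes; only one may join
        sets = [PredictionSet(0, [det(10, 10, 20, 20, 0.9)]),
                PredictionSet(1, [det(10, 10, 20, 20, 0.8),
                                  det(10.5, 10, 20.5, 20, 0.7)])]
        fused = vme_fuse(sets, VMEConfig(tau=0.5))
        # cluster of 2 (one per source) kept; leftover box forms its own
        # cluster of 1 which also survives (1 > floor(2/2) is false) ->
        # exactly one fused box
        assert len(fused) == 1
        assert fused[0].confidence == pytest.approx(0.85)


class TestOracleEquivalence:
    def _assert_same(self, a, b):
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.box.as_array() == pytest.approx(y.box.as_array(),
                                                     abs=1e-9)
            assert x.confidence == pytest.approx(y.confidence, abs=1e-9)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for trial in range(300):
            k = int(rng.integers(1, 6))
            tau = float(rng.uniform(0.2, 0.8))
            sets = random_sets(rng, k)
            self._assert_same(vme_fuse(sets, VMEConfig(tau=tau)),
                              vme_fuse_oracle(sets, VMEConfig(tau=tau)))

    def test_oracle_refuses_large_instances(self, rng):
        sets = random_sets(rng, 20, max_boxes_per_set=6)
        total = sum(len(s.detections) for s in sets)
        if total > 50:
            with pytest.raises(ValueError):
                vme_fuse_oracle(sets)


class TestFusionProperties:
    def test_permutation_invariance(self, rng):
        for _ in range(30):
            sets = random_sets(rng, 4)
            base = vme_fuse(sets)
            perm = [sets[i] for i in rng.permutation(4)]
            perm = [PredictionSet(p.source, list(rng.permutation(
                np.array(p.detections, dtype=object)))) for p in perm]
            out = vme_fuse(perm)
            key = lambda d: (round(d.confidence, 9),
                             tuple(np.round(d.box.as_array(), 9)))
            assert sorted(map(key, base)) == sorted(map(key, out))

    def test_raising_tau_never_keeps_more_clusters(self, rng):
        for _ in range(30):
            sets = random_sets(rng, 3)
            counts = [len(vme_fuse(sets, VMEConfig(tau=t)))
                      for t in (0.3, 0.5, 0.7)]
            assert counts == sorted(counts, reverse=True)

    def test_fused_boxes_inside_member_hull(self, rng):
        for _ in range(30):
            sets = random_sets(rng, 3)
            all_boxes = np.array(
                [d.box.as_array() for s in sets for d in s.detections])
            if all_boxes.size == 0:
                continue
            for f in vme_fuse(sets):
                b = f.box.as_array()
                assert b[0] >= all_boxes[:, 0].min() - 1e-9
                assert b[1] >= all_boxes[:, 1].min() - 1e-9
                assert b[2] <= all_boxes[:, 2].max() + 1e-9
                assert b[3] <= all_boxes[:, 3].max() + 1e-9


class _BrightSpotDetector:
    """Test oracle: finds the single bright square in an image exactly."""

    def detect(self, image, **kw):
        mask = image[..., 0] > 0.9
        ys, xs = np.nonzero(mask)
        if len(xs) == 0:
            return []
        return [Detection(Box(float(xs.min()), float(ys.min()),
                              float(xs.max() + 1), float(ys.max() + 1)),
                          confidence=0.9)]


class TestTTA:
    @pytest.fixture
    def spot_image(self):
        img = np.full((40, 60, 3), 0.2)     # non-square on purpose
        img[10:18, 35:47] = 1.0
        return img

    def test_identity_equals_direct_detection(self, spot_image):
        detector = _BrightSpotDetector()
        sets = tta_predict(detector, spot_image, ["identity"])
        assert len(sets) == 1
        direct = detector.detect(spot_image)
        assert sets[0].detections[0].box == direct[0].box

    @pytest.mark.parametrize("tag", ["flip_lr", "flip_ud", "rot90"])
    def test_augmented_boxes_map_back_exactly(self, spot_image, tag):
        detector = _BrightSpotDetector()
        (ps,) = tta_predict(detector, spot_image, [tag])
        direct = detector.detect(spot_image)[0].box
        mapped = ps.detections[0].box
        assert mapped.as_array() == pytest.approx(direct.as_array(),
                                                  abs=1e-9)

    def test_flip_of_flip_is_identity_on_boxes(self):
        _, back = AUGMENTATIONS["flip_lr"]
        b = Box(3.5, 7.25, 20.0, 31.5)
        assert back(back(b, 64, 48), 64, 48).as_array() == pytest.approx(
            b.as_array(), abs=1e-12)

    def test_unknown_augmentation_rejected(self, spot_image):
        with pytest.raises(ValueError):
            tta_predict(_BrightSpotDetector(), spot_image, ["zoom"])

    def test_tta_on_trained_detector_symmetric_scene(self, clean_detector,
                                                     scene64):
        img = scene64[0].copy()
        sym = np.concatenate([img[:, :32], img[:, :32][:, ::-1]], axis=1)
        sets = tta_predict(clean_detector, sym, ["identity", "flip_lr"],
                           confidence_threshold=0.5)
        direct = np.array([d.box.as_array() for d in sets[0].detections])
        mapped = np.array([d.box.as_array() for d in sets[1].detections])
        # a horizontally symmetric scene: flipped predictions map back
        # onto the direct ones, up to the detector's stride-8 grid
        # quantization (half-cell misalignment caps attainable IoU)
        from dynacolor.toy_detector import iou_matrix
        assert len(direct) and len(mapped)
        best = iou_matrix(direct, mapped).max(axis=1)
        assert (best > 0.5).all()
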