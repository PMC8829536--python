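"""Voting-based model ensemble (VME) and test-time augmentation.

Given K prediction sets for the same image (from K models, or from one
model run on K augmented views mapped back to original coordinates),
boxes are clustered across sets by IoU similarity; a cluster survives
only when strictly more than floor(K/2) sources support it — a
majority vote — and each surviving cluster is collapsed to a single
detection by averaging member coordinates and confidences.

Clustering is greedy: the highest-confidence unassigned box seeds a
cluster and absorbs, per source set, at most one unassigned box whose
IoU with the seed exceeds the similarity threshold (default 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .toy_detector import Box, Detection, iou, iou_matrix

__all__ = ["PredictionSet", "VMEConfig", "tta_predict", "vme_fuse",
           "vme_fuse_oracle", "AUGMENTATIONS"]


@dataclass(frozen=True)
class PredictionSet:
    """Detections of one ensemble member (source ids must be distinct)."""

    source: int
    detections: list = field(default_factory=list)


@dataclass(frozen=True)
class VMEConfig:
    """``tau``: IoU above which two boxes count as the same object."""

    tau: float = 0.6

    def __post_init__(self):
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0,1): {self.tau}")


# ---------------------------------------------------------------------------
# test-time augmentation

def _flip_lr_box(b: Box, w: int, h: int) -> Box:
    return Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max)


def _flip_ud_box(b: Box, w: int, h: int) -> Box:
    return Box(b.x_min, h - b.y_max, b.x_max, h - b.y_min)


def _rot90_box_inv(b: Box, w: int, h: int) -> Box:
    # inverse of np.rot90(image, 1): a point (x', y') in the rotated
    # (w x h -> h-wide) frame came from (x, y) = (w - y', x')
    return Box(w - b.y_max, b.x_min, w - b.y_min, b.x_max)


AUGMENTATIONS = {
    "identity": (lambda im: im, lambda b, w, h: b),
    "flip_lr": (lambda im: im[:, ::-1], _flip_lr_box),
    "flip_ud": (lambda im: im[::-1], _flip_ud_box),
    "rot90": (lambda im: np.rot90(im, 1), _rot90_box_inv),
}


def tta_predict(detector, image: np.ndarray,
                augmentations=("identity", "flip_lr", "flip_ud"),
                **detect_kwargs) -> list[PredictionSet]:
    """One prediction set per augmentation, boxes mapped back.

    Augmentation tags: ``identity``, ``flip_lr``, ``flip_ud``,
    ``rot90``.  Detections are re-expressed in original-image
    coordinates, so the K sets are directly comparable.
    """
    h, w = image.shape[:2]
    sets = []
    for i, tag in enumerate(augmentations):
        if tag not in AUGMENTATIONS:
            raise ValueError(f"unknown augmentation {tag!r}; "
                             f"choose from {sorted(AUGMENTATIONS)}")
        fwd, back = AUGMENTATIONS[tag]
        view = np.ascontiguousarray(fwd(image))
        dets = detector.detect(view, **detect_kwargs)
        mapped = [Detection(box=back(d.box, w, h),
                            confidence=d.confidence,
                            class_label=d.class_label) for d in dets]
        sets.append(PredictionSet(source=i, detections=mapped))
    return sets


# ---------------------------------------------------------------------------
# fusion

def _flatten(sets: list[PredictionSet]):
    """(source, Detection) pairs sorted by descending confidence.

    Ties broken by input order (set order, then in-set order) so the
    procedure is deterministic.
    """
    items = [(ps.source, d) for ps in sets for d in ps.detections]
    return sorted(items, key=lambda t: -t[1].confidence)


def _fuse_cluster(members) -> Detection:
    arr = np.array([d.box.as_array() for _, d in members])
    conf = float(np.mean([d.confidence for _, d in members]))
    return Detection(box=Box(*arr.mean(axis=0)), confidence=conf,
                     class_label=members[0][1].class_label)


def vme_fuse(sets: list[PredictionSet],
             config: VMEConfig | None = None) -> list[Detection]:
    """Cluster boxes across the K sets and keep majority-supported ones.

    A cluster (seed included) must have more than floor(K/2) members to
    survive; each surviving cluster becomes one detection with mean
    coordinates and mean confidence.  Output sorted by descending
    confidence.
    """
    if not sets:
        raise ValueError("empty ensemble: need at least one prediction set")
    if len({ps.source for ps in sets}) != len(sets):
        raise ValueError("prediction-set source ids must be distinct")
    config = config or VMEConfig()
    k = len(sets)
    need = k // 2           # keep iff cluster size > need
    items = _flatten(sets)
    boxes = (np.array([d.box.as_array() for _, d in items])
             if items else np.zeros((0, 4)))
    assigned = np.zeros(len(items), dtype=bool)
    fused: list[Detection] = []
    for i in range(len(items)):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [items[i]]
        used_sources = {items[i][0]}
        sims = iou_matrix(boxes[i:i + 1], boxes)[0]
        for j in range(len(items)):
            if assigned[j] or items[j][0] in used_sources:
                continue
            if sims[j] > config.tau:
                assigned[j] = True
                members.append(items[j])
                used_sources.add(items[j][0])
        if len(members) > need:
            fused.append(_fuse_cluster(members))
    return sorted(fused, key=lambda d: -d.confidence)


def vme_fuse_oracle(sets: list[PredictionSet],
                    config: VMEConfig | None = None,
                    max_boxes: int = 50) -> list[Detection]:
    """Plain-loop reimplementation of the fusion rule (test oracle).

    Same clustering semantics as :func:`vme_fuse`, written with
    explicit pairwise loops and scalar IoU; refuses instances larger
    than ``max_boxes`` boxes in total.
    """
    if not sets:
        raise ValueError("empty ensemble: need at least one prediction set")
    config = config or VMEConfig()
    items = _flatten(sets)
    if len(items) > max_boxes:
        raise ValueError(f"oracle limited to {max_boxes} boxes, "
                         f"got {len(items)}")
    k = len(sets)
    remaining = list(range(len(items)))
    fused = []
    while remaining:
        seed = remaining.pop(0)     # highest-confidence unassigned
        members = [items[seed]]
        sources = {items[seed][0]}
        still = []
        for idx in remaining:
            src, det = items[idx]
            if src not in sources and \
                    iou(items[seed][1].box, det.box) > config.tau:
                members.append(items[idx])
                sources.add(src)
            else:
                still.append(idx)
        remaining = still
        if len(members) > k // 2:
            arr = [m[1].box.as_array() for m in members]
            mean_box = [sum(c[d] for c in arr) / len(arr) for d in range(4)]
            mean_conf = sum(m[1].confidence for m in members) / len(members)
            fused.append(Detection(box=Box(*mean_box),
                                   confidence=mean_conf,
                                   class_label=members[0][1].class_label))
    return sorted(fused, key=lambda d: -d.confidence)
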