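"""Average Domain Accuracy (ADA) evaluation.

Per image, predictions are matched one-to-one to ground-truth boxes
greedily (descending confidence, best IoU first, IoU strictly above
the threshold, default 0.5) and accuracy is ``TP / (TP + FN + FP)``.
Per-image accuracies are averaged within each domain, and ADA is the
unweighted mean of the domain accuracies — so a small domain counts as
much as a large one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .toy_detector import Box, Detection, iou_matrix

__all__ = ["ImageEvalResult", "EvalReport", "match_detections",
           "image_accuracy", "ada", "evaluate_detector"]


@dataclass(frozen=True)
class ImageEvalResult:
    """True-positive / false-negative / false-positive counts."""

    tp: int
    fn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvalReport:
    per_image: dict                 # image id -> ImageEvalResult
    per_image_accuracy: dict        # image id -> float
    per_domain: dict                # domain -> mean accuracy
    domain_sizes: dict              # domain -> image count
    ada: float

    def summary(self) -> str:
        lines = ["domain\tn_images\taccuracy"]
        for dom, acc in sorted(self.per_domain.items()):
            lines.append(f"{dom}\t{self.domain_sizes.get(dom, 0)}\t{acc:.4f}")
        lines.append(f"ADA\t\t{self.ada:.4f}")
        return "\n".join(lines)


def match_detections(predictions: list[Detection], truths: list[Box],
                     iou_threshold: float = 0.5) -> ImageEvalResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are processed in descending confidence (stable in the
    input order on ties); each claims the yet-unmatched truth with the
    highest IoU, provided that IoU exceeds the threshold strictly.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must be in (0,1): {iou_threshold}")
    n_truth = len(truths)
    if not predictions:
        return ImageEvalResult(tp=0, fn=n_truth, fp=0)
    order = sorted(range(len(predictions)),
                   key=lambda i: -predictions[i].confidence)
    pred_arr = np.array([predictions[i].box.as_array() for i in order])
    truth_arr = (np.array([Box(*t.as_array()).as_array() if isinstance(t, Box)
                           else np.asarray(t, float) for t in truths])
                 if truths else np.zeros((0, 4)))
    mat = iou_matrix(pred_arr, truth_arr) if n_truth else None
    matched = np.zeros(n_truth, dtype=bool)
    tp = 0
    for row in range(len(predictions)):
        if mat is None:
            break
        ious = np.where(matched, -1.0, mat[row])
        j = int(np.argmax(ious)) if n_truth else -1
        if j >= 0 and ious[j] > iou_threshold:
            matched[j] = True
            tp += 1
    return ImageEvalResult(tp=tp, fn=n_truth - tp, fp=len(predictions) - tp)


def image_accuracy(result: ImageEvalResult) -> float:
    """``TP / (TP + FN + FP)``; 1.0 for an empty image with no predictions."""
    total = result.tp + result.fn + result.fp
    if total == 0:
        return 1.0
    return result.tp / total


def ada(per_image_results: dict, domains: dict) -> EvalReport:
    """Two-level unweighted mean: images within domain, then domains.

    ``per_image_results`` maps image id -> :class:`ImageEvalResult`;
    ``domains`` maps image id -> domain label (every image needs one).
    """
    missing = set(per_image_results) - set(domains)
    if missing:
        raise ValueError(f"images without a domain label: {sorted(missing)}")
    accs = {k: image_accuracy(r) for k, r in per_image_results.items()}
    by_domain: dict[str, list[float]] = {}
    sizes: dict[str, int] = {}
    for k, acc in accs.items():
        dom = domains[k]
        by_domain.setdefault(dom, []).append(acc)
        sizes[dom] = sizes.get(dom, 0) + 1
    per_domain = {d: float(np.mean(v)) for d, v in by_domain.items()}
    return EvalReport(
        per_image=dict(per_image_results),
        per_image_accuracy=accs,
        per_domain=per_domain,
        domain_sizes=sizes,
        ada=float(np.mean(list(per_domain.values()))),
    )


def evaluate_detector(detector, samples, iou_threshold: float = 0.5,
                      transform=None, predictions=None) -> EvalReport:
    """Evaluate a detector (or precomputed predictions) on samples.

    ``transform`` is an optional callable ``image -> image`` applied
    before detection (e.g. a fixed or predicted color transform);
    ``predictions`` may supply a mapping image id -> list[Detection]
    to skip running the detector.
    """
    results, domains = {}, {}
    for s in samples:
        if predictions is not None:
            dets = predictions.get(s.image_id, [])
        else:
            img = s.image if transform is None else transform(s.image)
            dets = detector.detect(img)
        results[s.image_id] = match_detections(dets, s.boxes, iou_threshold)
        domains[s.image_id] = s.domain
    return ada(results, domains)
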