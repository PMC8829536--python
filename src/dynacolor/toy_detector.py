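"""Box geometry, detection losses, and a minimal dense detector.

The detector contract used throughout the package is: any object with a
``detect(image) -> list[Detection]`` method.  The :class:`ToyDetector`
here is a deliberately small single-scale anchor-free convnet — one
objectness logit and four box offsets per grid cell — sufficient to
exercise color-transform training, ensembling and evaluation end to end
on a CPU.  It is *not* a reimplementation of a production detector.

Loss composition follows the standard one-stage recipe: binary
cross-entropy on per-cell objectness plus ``1 - GIoU`` averaged over
positive cells; a cell with no assigned ground-truth box contributes no
localization loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nnops import SGDMomentum, conv2d, conv2d_backward, relu, sigmoid

__all__ = [
    "Box", "Detection", "iou", "giou", "iou_matrix",
    "assign_targets", "GridTargets", "detection_loss",
    "ToyDetector", "toy_detect", "nms",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in continuous pixel coordinates (origin top-left)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(c) for c in coords):
            raise ValueError(f"box coordinates must be finite: {coords}")
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError(f"degenerate box: {coords}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max),
                0.5 * (self.y_min + self.y_max))

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])


@dataclass(frozen=True)
class Detection:
    """A predicted box with a confidence score (single class by default)."""

    box: Box
    confidence: float
    class_label: int = 0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1]: {self.confidence}")


def _as_box(b) -> Box:
    if isinstance(b, Box):
        return b
    return Box(*np.asarray(b, dtype=float))


def iou(a, b) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    a, b = _as_box(a), _as_box(b)
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def giou(a, b) -> float:
    """Generalized IoU: IoU minus the normalized slack of the hull.

    ``giou = IoU - (area(hull) - area(union)) / area(hull)``; equals IoU
    when the union fills the smallest enclosing box, and tends to -1 for
    far-apart boxes.
    """
    a, b = _as_box(a), _as_box(b)
    i = iou(a, b)
    inter = i / (1 + i) * (a.area + b.area) if i > 0 else 0.0
    union = a.area + b.area - inter
    hull = ((max(a.x_max, b.x_max) - min(a.x_min, b.x_min))
            * (max(a.y_max, b.y_max) - min(a.y_min, b.y_min)))
    return i - (hull - union) / hull


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M,4) and (N,4) box arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def _giou_and_grad(pred: np.ndarray, tgt: np.ndarray):
    """Vectorized GIoU of matched (M,4) box pairs and d(giou)/d(pred)."""
    px0, py0, px1, py1 = pred.T
    tx0, ty0, tx1, ty1 = tgt.T
    wp, hp = px1 - px0, py1 - py0
    ix0, iy0 = np.maximum(px0, tx0), np.maximum(py0, ty0)
    ix1, iy1 = np.minimum(px1, tx1), np.minimum(py1, ty1)
    iw, ih = np.clip(ix1 - ix0, 0, None), np.clip(iy1 - iy0, 0, None)
    inter = iw * ih
    area_p = wp * hp
    area_t = (tx1 - tx0) * (ty1 - ty0)
    union = area_p + area_t - inter
    cw = np.maximum(px1, tx1) - np.minimum(px0, tx0)
    ch = np.maximum(py1, ty1) - np.minimum(py0, ty0)
    hull = cw * ch
    g = inter / union - (hull - union) / hull

    pos = inter > 0
    di_x0 = np.where(pos & (px0 > tx0), -ih, 0.0)
    di_x1 = np.where(pos & (px1 < tx1), ih, 0.0)
    di_y0 = np.where(pos & (py0 > ty0), -iw, 0.0)
    di_y1 = np.where(pos & (py1 < ty1), iw, 0.0)
    da_x0, da_x1 = -hp, hp
    da_y0, da_y1 = -wp, wp
    dc_x0 = np.where(px0 < tx0, -ch, 0.0)
    dc_x1 = np.where(px1 > tx1, ch, 0.0)
    dc_y0 = np.where(py0 < ty0, -cw, 0.0)
    dc_y1 = np.where(py1 > ty1, cw, 0.0)

    grad = np.empty_like(pred)
    for k, (di, da, dc) in enumerate([
            (di_x0, da_x0, dc_x0), (di_y0, da_y0, dc_y0),
            (di_x1, da_x1, dc_x1), (di_y1, da_y1, dc_y1)]):
        du = da - di
        # d[I/U] + d[U/C]   (giou = I/U - 1 + U/C)
        grad[:, k] = (di / union - inter * du / union**2
                      + du / hull - union * dc / hull**2)
    return g, grad


@dataclass
class GridTargets:
    """Per-cell training targets for the toy detector's grid."""

    objectness: np.ndarray   # (Hg, Wg) in {0, 1}
    boxes: np.ndarray        # (Hg, Wg, 4), valid where objectness == 1

    @property
    def n_positive(self) -> int:
        return int(self.objectness.sum())


def assign_targets(boxes, grid_h: int, grid_w: int, stride: int) -> GridTargets:
    """Assign each ground-truth box to the grid cell holding its center.

    When several box centers land in one cell, the box whose center is
    closest to the cell center wins; ties go to the smaller box.
    """
    obj = np.zeros((grid_h, grid_w))
    tgt = np.zeros((grid_h, grid_w, 4))
    best = {}
    for b in boxes:
        b = _as_box(b)
        cx, cy = b.center
        gx, gy = int(cx // stride), int(cy // stride)
        if not (0 <= gx < grid_w and 0 <= gy < grid_h):
            continue
        ccx, ccy = (gx + 0.5) * stride, (gy + 0.5) * stride
        key = (gy, gx)
        rank = ((cx - ccx) ** 2 + (cy - ccy) ** 2, b.area)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, b)
    for (gy, gx), (_, b) in best.items():
        obj[gy, gx] = 1.0
        tgt[gy, gx] = b.as_array()
    return GridTargets(objectness=obj, boxes=tgt)


def detection_loss(predictions: np.ndarray, targets: GridTargets,
                   stride: int, box_base: float):
    """Classification (BCE) and localization (1 - GIoU) losses on a grid.

    ``predictions`` is the raw (5, Hg, Wg) map: channel 0 the objectness
    logit, channels 1..4 the box offsets decoded as in
    :meth:`ToyDetector.decode`.  Returns ``(loss_cls, loss_loc)``.
    """
    if predictions.size == 0:
        raise ValueError("empty prediction grid")
    (loss_cls, loss_loc), _ = _loss_and_grid_grad(
        predictions[None], [targets], stride, box_base)
    return loss_cls, loss_loc


def _decode_boxes(raw: np.ndarray, stride: int, box_base: float):
    """(N,5,Hg,Wg) raw maps -> per-cell boxes (N,Hg,Wg,4) + objectness."""
    n, _, hg, wg = raw.shape
    obj = sigmoid(raw[:, 0])
    sx, sy = sigmoid(raw[:, 1]), sigmoid(raw[:, 2])
    gx = np.arange(wg)[None, None, :]
    gy = np.arange(hg)[None, :, None]
    cx = (gx + sx) * stride
    cy = (gy + sy) * stride
    tw = np.clip(raw[:, 3], -6, 6)
    th = np.clip(raw[:, 4], -6, 6)
    w = box_base * np.exp(tw)
    h = box_base * np.exp(th)
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)
    return obj, boxes, (sx, sy, w, h, tw, th)


def _loss_and_grid_grad(raw: np.ndarray, targets_list, stride: int,
                        box_base: float):
    """Batch loss and gradient w.r.t. the raw (N,5,Hg,Wg) maps."""
    n, _, hg, wg = raw.shape
    obj, boxes, (sx, sy, w, h, tw, th) = _decode_boxes(raw, stride, box_base)
    tgt_obj = np.stack([t.objectness for t in targets_list])
    tgt_box = np.stack([t.boxes for t in targets_list])

    n_cells = n * hg * wg
    eps = 1e-12
    loss_cls = -np.mean(tgt_obj * np.log(obj + eps)
                        + (1 - tgt_obj) * np.log(1 - obj + eps))
    draw = np.zeros_like(raw)
    draw[:, 0] = (obj - tgt_obj) / n_cells

    pos = tgt_obj > 0.5
    n_pos = int(pos.sum())
    if n_pos == 0:
        return (float(loss_cls), 0.0), draw
    g, dg = _giou_and_grad(boxes[pos], tgt_box[pos])
    loss_loc = float(np.mean(1.0 - g))
    dbox = -dg / n_pos                      # d loss_loc / d box coords
    # chain through the decode: cx = (gx + sigmoid(tx)) * stride, w = base*e^tw
    dcx = dbox[:, 0] + dbox[:, 2]
    dcy = dbox[:, 1] + dbox[:, 3]
    dw = 0.5 * (dbox[:, 2] - dbox[:, 0])
    dh = 0.5 * (dbox[:, 3] - dbox[:, 1])
    sxp, syp = sx[pos], sy[pos]
    interior_w = (np.abs(tw[pos]) < 6)      # clip kills the gradient outside
    interior_h = (np.abs(th[pos]) < 6)
    dtx = dcx * stride * sxp * (1 - sxp)
    dty = dcy * stride * syp * (1 - syp)
    dtw = np.where(interior_w, dw * w[pos], 0.0)
    dth = np.where(interior_h, dh * h[pos], 0.0)
    for ch, dv in zip(range(1, 5), (dtx, dty, dtw, dth)):
        plane = np.zeros((n, hg, wg))
        plane[pos] = dv
        draw[:, ch] = plane
    return (float(loss_cls), loss_loc), draw


def nms(detections: list[Detection], iou_threshold: float = 0.5
        ) -> list[Detection]:
    """Greedy non-maximum suppression, highest confidence first."""
    dets = sorted(detections, key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for d in dets:
        if all(iou(d.box, k.box) <= iou_threshold for k in kept):
            kept.append(d)
    return kept


class ToyDetector:
    """Single-scale anchor-free dense detector (stride 8, 4 conv layers).

    Per grid cell it emits an objectness logit and four box offsets:
    the cell-relative center through a sigmoid, and log-scale width and
    height around ``box_base`` pixels.
    """

    STRIDE = 8

    def __init__(self, seed: int = 0, box_base: float = 10.0,
                 channels: tuple[int, ...] = (16, 32, 32)):
        self.box_base = float(box_base)
        self.channels = tuple(channels)
        self.frozen = False
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.channels
        def init(co, ci, k):
            fan_in = ci * k * k
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), (co, ci, k, k))
        self.params = {
            "w1": init(c1, 3, 3), "b1": np.zeros(c1),
            "w2": init(c2, c1, 3), "b2": np.zeros(c2),
            "w3": init(c3, c2, 3), "b3": np.zeros(c3),
            "w4": init(5, c3, 1) * 0.1, "b4": np.zeros(5),
        }

    # -- forward ---------------------------------------------------------
    def forward(self, images: np.ndarray):
        """(N,H,W,3) in [0,1]-ish -> raw (N,5,Hg,Wg) maps + cache."""
        x = np.ascontiguousarray(images.transpose(0, 3, 1, 2))
        p = self.params
        z1, c1 = conv2d(x, p["w1"], p["b1"], stride=2, pad=1)
        a1 = relu(z1)
        z2, c2 = conv2d(a1, p["w2"], p["b2"], stride=2, pad=1)
        a2 = relu(z2)
        z3, c3 = conv2d(a2, p["w3"], p["b3"], stride=2, pad=1)
        a3 = relu(z3)
        raw, c4 = conv2d(a3, p["w4"], p["b4"], stride=1, pad=0)
        cache = (c1, z1, c2, z2, c3, z3, c4)
        return raw, cache

    def backward(self, draw: np.ndarray, cache, need_dinput: bool = False):
        """Backprop d(loss)/d(raw maps) to parameter (and input) grads."""
        c1, z1, c2, z2, c3, z3, c4 = cache
        p = self.params
        grads = {}
        d3, grads["w4"], grads["b4"] = conv2d_backward(draw, c4, p["w4"])
        d3 = d3 * (z3 > 0)
        d2, grads["w3"], grads["b3"] = conv2d_backward(d3, c3, p["w3"])
        d2 = d2 * (z2 > 0)
        d1, grads["w2"], grads["b2"] = conv2d_backward(d2, c2, p["w2"])
        d1 = d1 * (z1 > 0)
        dx, grads["w1"], grads["b1"] = conv2d_backward(
            d1, c1, p["w1"], need_dx=need_dinput)
        if need_dinput and dx is not None:
            dx = dx.transpose(0, 2, 3, 1)
        return grads, dx

    def loss(self, images: np.ndarray, boxes_per_image,
             with_grads: bool = True):
        """Total loss over a batch; optionally parameter gradients."""
        raw, cache = self.forward(images)
        hg, wg = raw.shape[2], raw.shape[3]
        targets = [assign_targets(b, hg, wg, self.STRIDE)
                   for b in boxes_per_image]
        (lc, ll), draw = _loss_and_grid_grad(
            raw, targets, self.STRIDE, self.box_base)
        if not with_grads:
            return lc, ll, None
        grads, _ = self.backward(draw, cache)
        return lc, ll, grads

    def input_gradient(self, images: np.ndarray, boxes_per_image):
        """Loss and its gradient w.r.t. the input images (params frozen)."""
        raw, cache = self.forward(images)
        hg, wg = raw.shape[2], raw.shape[3]
        targets = [assign_targets(b, hg, wg, self.STRIDE)
                   for b in boxes_per_image]
        (lc, ll), draw = _loss_and_grid_grad(
            raw, targets, self.STRIDE, self.box_base)
        _, dx = self.backward(draw, cache, need_dinput=True)
        return (lc, ll), dx

    # -- inference -------------------------------------------------------
    def detect(self, image: np.ndarray, confidence_threshold: float = 0.5,
               nms_iou: float = 0.5) -> list[Detection]:
        return toy_detect(self, image, confidence_threshold, nms_iou)

    def freeze(self) -> "ToyDetector":
        self.frozen = True
        return self

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def make_optimizer(self, lr: float, momentum: float = 0.9) -> SGDMomentum:
        if self.frozen:
            raise RuntimeError("detector is frozen; cannot optimize")
        return SGDMomentum(self.params, lr=lr, momentum=momentum)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(path, box_base=self.box_base,
                            channels=np.array(self.channels), **self.params)

    @classmethod
    def load(cls, path) -> "ToyDetector":
        with np.load(path) as data:
            det = cls(box_base=float(data["box_base"]),
                      channels=tuple(int(c) for c in data["channels"]))
            for k in det.params:
                det.params[k] = data[k].copy()
        return det


def toy_detect(model: ToyDetector, image: np.ndarray,
               confidence_threshold: float = 0.5,
               nms_iou: float = 0.5) -> list[Detection]:
    """Run the toy detector on one image: decode, threshold, NMS.

    Detections are returned sorted by descending confidence.
    """
    if image.shape[0] < model.STRIDE or image.shape[1] < model.STRIDE:
        raise ValueError(
            f"image {image.shape[:2]} smaller than one grid cell "
            f"({model.STRIDE}px)")
    raw, _ = model.forward(image[None])
    obj, boxes, _ = _decode_boxes(raw, model.STRIDE, model.box_base)
    conf = obj[0].ravel()
    flat = boxes[0].reshape(-1, 4)
    keep = conf > confidence_threshold
    dets = []
    for c, b in zip(conf[keep], flat[keep]):
        try:
            dets.append(Detection(box=Box(*b), confidence=float(c)))
        except ValueError:
            continue   # numerically degenerate decode; drop
    return nms(dets, iou_threshold=nms_iou)
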