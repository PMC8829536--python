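"""Two-step training: detector first, then the color-transform network.

Step one trains the dense detector on annotated images with basic
augmentation (flips, scale jitter, brightness/contrast jitter).  Step
two freezes the detector and trains the transform network through it:
each image is mapped to ``(alpha, beta)``, transformed (no clipping,
so the map stays linear and gradients flow), pushed through the frozen
detector, and the detection loss is back-propagated through the
transform into the transform network's parameters only.

Also here: the fixed-transform color sweep (apply one global
``(alpha, beta)`` to every test image, evaluate, tabulate) and minimal
pseudolabeling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._nnops import SGDMomentum, sigmoid
from .color_transform import TransformParams, apply_color_transform
from .dct_network import DCTNetwork
from .evaluation import evaluate_detector
from .synthetic_data import Sample
from .toy_detector import Box, ToyDetector

__all__ = ["TrainConfig", "train_detector", "train_dct", "color_sweep",
           "make_pseudolabels"]


@dataclass
class TrainConfig:
    """Optimization settings for either training step.

    ``steps`` counts gradient steps (desk scale); the schedules of the
    full-scale recipe (cosine annealing for the detector, step decay
    /10 every third of training for the transform) are available via
    ``lr_schedule`` in {"constant", "cosine", "step"}.
    """

    steps: int = 300
    lr: float = 0.05
    lr_schedule: str = "constant"
    batch_size: int = 4
    momentum: float = 0.9
    augment_flip: bool = True
    augment_scale: bool = True
    augment_color: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1 or self.lr <= 0 or self.batch_size < 1:
            raise ValueError("steps, lr and batch_size must be positive")
        if self.lr_schedule not in ("constant", "cosine", "step"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    def lr_at(self, step: int) -> float:
        if self.lr_schedule == "cosine":
            return self.lr * 0.5 * (1 + np.cos(np.pi * step / self.steps))
        if self.lr_schedule == "step":
            return self.lr * 10.0 ** (-(3 * step) // self.steps)
        return self.lr


def _augment(image: np.ndarray, boxes: list[Box], rng, config: TrainConfig):
    h, w = image.shape[:2]
    arr = np.array([b.as_array() for b in boxes]) if boxes else np.zeros((0, 4))
    if config.augment_flip and rng.random() < 0.5:
        image = image[:, ::-1]
        arr = arr.copy()
        arr[:, [0, 2]] = w - arr[:, [2, 0]]
    if config.augment_flip and rng.random() < 0.5:
        image = image[::-1]
        arr = arr.copy()
        arr[:, [1, 3]] = h - arr[:, [3, 1]]
    if config.augment_scale and rng.random() < 0.5:
        s = rng.uniform(0.85, 1.15)
        nh, nw = max(int(h * s), 16), max(int(w * s), 16)
        yy = np.clip((np.arange(nh) / s).astype(int), 0, h - 1)
        xx = np.clip((np.arange(nw) / s).astype(int), 0, w - 1)
        image = image[np.ix_(yy, xx)]
        arr = arr * [nw / w, nh / h, nw / w, nh / h]
        # pad or crop back to the original frame
        out = np.empty((h, w, 3))
        out[:] = image[0, 0]
        ch, cw = min(h, nh), min(w, nw)
        out[:ch, :cw] = image[:ch, :cw]
        image = out
        arr = np.clip(arr, [0, 0, 0, 0], [w, h, w, h])
        arr = arr[(arr[:, 2] - arr[:, 0] > 1) & (arr[:, 3] - arr[:, 1] > 1)]
    if config.augment_color and rng.random() < 0.5:
        gain = rng.uniform(0.9, 1.1)
        shift = rng.uniform(-0.03, 0.03)
        image = np.clip(gain * image + shift, 0.0, 1.0)
    return np.ascontiguousarray(image), [Box(*row) for row in arr]


def train_detector(dataset: list[Sample], config: TrainConfig,
                   detector: ToyDetector | None = None):
    """Train the toy detector; returns ``(detector, history)``.

    ``history`` is a DataFrame with per-step classification and
    localization losses.  Reproducible given ``config.seed``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    detector = detector or ToyDetector(seed=config.seed)
    opt = detector.make_optimizer(config.lr, config.momentum)
    rows = []
    for step in range(config.steps):
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        images, boxes = [], []
        for i in idx:
            s = dataset[int(i)]
            im, bx = _augment(s.image, s.boxes, rng, config)
            images.append(im)
            boxes.append(bx)
        lc, ll, grads = detector.loss(np.stack(images), boxes)
        opt.lr = config.lr_at(step)
        opt.step(grads)
        rows.append({"step": step, "loss_cls": lc, "loss_loc": ll,
                     "loss": lc + ll})
    return detector, pd.DataFrame(rows)


def train_dct(dataset: list[Sample], frozen_detector: ToyDetector,
              dct: DCTNetwork, config: TrainConfig):
    """Train the transform network through a frozen detector.

    Only the transform network's parameters change; the detector
    provides the loss and its gradient with respect to the transformed
    image.  Raises if the detector is not frozen or the transform
    network is not trainable (conv encoders are inference-only).
    """
    if not dataset:
        raise ValueError("empty dataset")
    if not getattr(frozen_detector, "frozen", False):
        raise RuntimeError("detector must be frozen before DCT training "
                           "(call detector.freeze())")
    if not dct.trainable:
        raise RuntimeError("DCT network is not trainable; use the "
                           "toy_linear encoder for desk-scale training")
    if dct.formulation != "regression":
        raise NotImplementedError(
            "desk-scale DCT training supports the regression formulation")
    rng = np.random.default_rng(config.seed)
    opt = SGDMomentum(dct.parameters(), lr=config.lr,
                      momentum=config.momentum)
    cfg = dct.head_config
    rows = []
    for step in range(config.steps):
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        total_lc = total_ll = 0.0
        grads_acc = {k: np.zeros_like(v) for k, v in dct.parameters().items()}
        for i in idx:
            s = dataset[int(i)]
            image, boxes = s.image, s.boxes
            if config.augment_flip and rng.random() < 0.5:
                w = image.shape[1]
                image = np.ascontiguousarray(image[:, ::-1])
                boxes = [Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max)
                         for b in boxes]
            z, cache = dct.forward_train(image)
            sig = float(sigmoid(np.array([z[0]]))[0])
            alpha = cfg.alpha_max * sig
            beta = cfg.beta_max * (2.0 / np.pi) * np.arctan(z[1])
            transformed = alpha * image + beta     # clip off: keep linear
            (lc, ll), dimg = frozen_detector.input_gradient(
                transformed[None], [boxes])
            dimg = dimg[0]
            dalpha = float(np.sum(dimg * image))
            dbeta = float(np.sum(dimg))
            dz = np.array([
                dalpha * cfg.alpha_max * sig * (1.0 - sig),
                dbeta * cfg.beta_max * (2.0 / np.pi) / (1.0 + z[1] ** 2),
            ])
            for k, g in dct.backward_train(dz, cache).items():
                grads_acc[k] += g / config.batch_size
            total_lc += lc / config.batch_size
            total_ll += ll / config.batch_size
        opt.lr = config.lr_at(step)
        opt.step(grads_acc)
        rows.append({"step": step, "loss_cls": total_lc,
                     "loss_loc": total_ll, "loss": total_lc + total_ll})
    return dct, pd.DataFrame(rows)


def color_sweep(detector, dataset: list[Sample], alpha_grid,
                beta_grid=(0.0,), iou_threshold: float = 0.5) -> pd.DataFrame:
    """Fixed-transform sweep: one evaluation per (alpha, beta) grid point.

    Each test image is transformed with the fixed global parameters
    (no clipping) before detection; returns a DataFrame with columns
    ``alpha``, ``beta``, ``ada`` in grid order.  The identity point
    (1.0, 0.0) reproduces the no-transform baseline exactly.
    """
    if not dataset:
        raise ValueError("empty dataset")
    alpha_grid, beta_grid = list(alpha_grid), list(beta_grid)
    if not alpha_grid or not beta_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for alpha, beta in itertools.product(alpha_grid, beta_grid):
        params = TransformParams(alpha=float(alpha), beta=float(beta))
        report = evaluate_detector(
            detector, dataset, iou_threshold=iou_threshold,
            transform=lambda im: apply_color_transform(im, params, clip=False))
        rows.append({"alpha": float(alpha), "beta": float(beta),
                     "ada": report.ada})
    return pd.DataFrame(rows)


def make_pseudolabels(detector, samples: list[Sample],
                      confidence_threshold: float = 0.5) -> list[Sample]:
    """Pair each image with its own thresholded detections as labels.

    Returned samples carry ``pseudo=True`` so downstream code can tell
    model-generated boxes from human annotation.
    """
    out = []
    for s in samples:
        dets = detector.detect(s.image,
                               confidence_threshold=confidence_threshold)
        out.append(Sample(image=s.image, boxes=[d.box for d in dets],
                          domain=s.domain, image_id=s.image_id,
                          clean_image=s.clean_image,
                          degradation=s.degradation, split=s.split,
                          pseudo=True))
    return out
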