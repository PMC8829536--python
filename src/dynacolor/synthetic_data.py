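"""Synthetic multi-domain field scenes with box annotations.

Emulates the statistical structure the color-transform method assumes:
small bright "head" objects (rotated ellipses with mild color jitter)
scattered over a darker green textured background, grouped into domains
that differ by a known global linear illumination degradation
``x_obs = a * x + b``.  Rendering is deliberately minimal — the point
is a controllable testbed where detection measurably degrades under
illumination shift and a global linear correction measurably helps,
not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .color_transform import as_rgb_image
from .toy_detector import Box, iou_matrix

__all__ = [
    "SceneConfig", "DegradationParams", "Sample", "Benchmark",
    "generate_scene", "apply_degradation", "generate_benchmark",
]


@dataclass(frozen=True)
class SceneConfig:
    """Rendering parameters for one synthetic scene.

    Defaults emulate a down-scaled field patch: a 128 px frame with
    5-15 heads of 3-7 px semi-axes, heads noticeably brighter (and
    yellower) than the green textured background.
    """

    height: int = 128
    width: int = 128
    n_objects: tuple[int, int] = (5, 15)
    semi_axis_range: tuple[float, float] = (3.0, 7.0)
    object_intensity: tuple[float, float] = (0.70, 0.92)
    background_intensity: float = 0.32
    texture_amplitude: float = 0.05
    color_jitter: float = 0.04
    max_overlap_iou: float = 0.25

    def __post_init__(self):
        if self.n_objects[0] < 0 or self.n_objects[0] > self.n_objects[1]:
            raise ValueError(f"bad object count range {self.n_objects}")
        lo, hi = self.semi_axis_range
        if 2 * hi >= min(self.height, self.width):
            raise ValueError(
                f"objects of semi-axis {hi} cannot fit in a "
                f"{self.height}x{self.width} frame")
        if not (0 <= self.background_intensity <= 1):
            raise ValueError("background intensity must be in [0,1]")


@dataclass(frozen=True)
class DegradationParams:
    """A global linear illumination degradation with a domain label."""

    a: float
    b: float = 0.0
    domain: str = "domain"

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"gain must be positive, got {self.a}")


@dataclass
class Sample:
    """One annotated image: clean and degraded views share the boxes."""

    image: np.ndarray              # degraded view (what the detector sees)
    boxes: list[Box]
    domain: str
    image_id: str
    clean_image: np.ndarray | None = None
    degradation: DegradationParams | None = None
    split: str = ""
    pseudo: bool = False           # boxes are model predictions, not truth


def _render_ellipse(image, mask_accum, cx, cy, ax, ay, angle, color, rng,
                    cfg):
    h, w = image.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0
    if not mask.any():
        return None
    shading = 1.0 - 0.25 * ((u / ax) ** 2 + (v / ay) ** 2)[mask]
    image[mask] = color[None, :] * shading[:, None]
    mask_accum |= mask
    ys, xs = np.nonzero(mask)
    # tight box around the rendered pixels (pixel centers at integers)
    return Box(float(xs.min()), float(ys.min()),
               float(xs.max() + 1), float(ys.max() + 1))


def generate_scene(config: SceneConfig, rng: np.random.Generator):
    """Render one scene; returns ``(image, boxes)``.

    Object positions are rejection-sampled so that candidate boxes
    overlap existing ones at IoU below ``config.max_overlap_iou``;
    reproducible given the generator state.
    """
    h, w = config.height, config.width
    base = config.background_intensity
    # green-tinted textured background
    texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=2.0)
    texture *= config.texture_amplitude / max(texture.std(), 1e-9)
    lum = base + texture + rng.normal(0.0, 0.01, (h, w))
    image = np.stack([0.75 * lum, 1.05 * lum, 0.55 * lum], axis=-1)

    n = int(rng.integers(config.n_objects[0], config.n_objects[1] + 1))
    boxes: list[Box] = []
    placed = np.zeros((0, 4))
    mask_accum = np.zeros((h, w), dtype=bool)
    lo, hi = config.semi_axis_range
    attempts = 0
    while len(boxes) < n and attempts < 60 * max(n, 1):
        attempts += 1
        ax = rng.uniform(lo, hi)
        ay = rng.uniform(lo, hi) * rng.uniform(1.2, 2.0)  # elongated heads
        ay = min(ay, hi * 2.0)
        r = max(ax, ay)
        cx = rng.uniform(r + 1, w - r - 1)
        cy = rng.uniform(r + 1, h - r - 1)
        cand = np.array([[cx - r, cy - r, cx + r, cy + r]])
        if placed.size and iou_matrix(cand, placed).max() > config.max_overlap_iou:
            continue
        u = rng.uniform(*config.object_intensity)
        jit = rng.normal(0.0, config.color_jitter, 3)
        color = np.clip(
            u * np.array([1.0, 0.92, 0.55]) + jit, 0.05, 1.0)  # straw yellow
        angle = rng.uniform(0, np.pi)
        box = _render_ellipse(image, mask_accum, cx, cy, ax, ay, angle,
                              color, rng, config)
        if box is None:
            continue
        boxes.append(box)
        placed = np.vstack([placed, cand])
    image = np.clip(image, 0.0, 1.0)
    return image, boxes


def apply_degradation(image, deg: DegradationParams,
                      clip: bool = True) -> np.ndarray:
    """Observe ``x_obs = a * x + b``; boxes are unaffected.

    Clipping on by default: real sensors saturate, which is exactly
    what makes the inverse correction nontrivial.
    """
    arr = as_rgb_image(image)
    out = deg.a * arr + deg.b
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


@dataclass
class Benchmark:
    """A multi-domain dataset with train/val/test splits."""

    samples: list[Sample]
    domains: list[DegradationParams]
    seed: int

    def split(self, name: str) -> list[Sample]:
        return [s for s in self.samples if s.split == name]

    @property
    def train(self) -> list[Sample]:
        return self.split("train")

    @property
    def val(self) -> list[Sample]:
        return self.split("val")

    @property
    def test(self) -> list[Sample]:
        return self.split("test")


def generate_benchmark(domains: list[tuple[SceneConfig, DegradationParams]],
                       images_per_domain: int,
                       split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                       seed: int = 0, clip: bool = True) -> Benchmark:
    """Generate a multi-domain benchmark with known degradations.

    Each domain gets ``images_per_domain`` scenes rendered clean and
    then degraded with its own ``(a, b)``; splits are disjoint with
    deterministic sizes (train and val rounded down, remainder to
    test).
    """
    if not domains:
        raise ValueError("need at least one domain")
    if images_per_domain < 1:
        raise ValueError("images_per_domain must be >= 1")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1: {split_fractions}")
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    n_train = int(images_per_domain * split_fractions[0])
    n_val = int(images_per_domain * split_fractions[1])
    for cfg, deg in domains:
        for i in range(images_per_domain):
            clean, boxes = generate_scene(cfg, rng)
            degraded = apply_degradation(clean, deg, clip=clip)
            split = ("train" if i < n_train
                     else "val" if i < n_train + n_val else "test")
            samples.append(Sample(
                image=degraded, boxes=boxes, domain=deg.domain,
                image_id=f"{deg.domain}_{i:04d}", clean_image=clean,
                degradation=deg, split=split))
    return Benchmark(samples=samples, domains=[d for _, d in domains],
                     seed=seed)
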