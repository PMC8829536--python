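"""CNN feature extractors for the color-transform network.

Four canonical image encoders — resnet18, resnet34, mobilenet_v2 and
shufflenet_v2 (1.0x) — are built as NumPy layer stacks with their
published stage layouts, truncated before the classifier, so their
trainable parameter counts are exactly those of the standard feature
extractors.  They run inference on CPU; they are not trainable here.
A fifth family, ``toy_linear`` (a per-pixel linear map followed by
global average pooling), is fully differentiable by hand and is the
encoder used when the transform network is actually trained at desk
scale.

All encoders consume an H x W x 3 image in [0, 1] and expose
``pooled_features(image) -> (C,) vector`` (global average pooling of
the final feature map) plus ``trainable_arrays()`` for counting and
checkpointing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nnops import conv2d, im2col, relu

__all__ = ["EncoderSpec", "build_encoder", "ENCODER_CHANNELS",
           "ToyLinearEncoder"]

ENCODER_CHANNELS = {
    "resnet18": 512,
    "resnet34": 512,
    "mobilenet_v2": 1280,
    "shufflenet_v2": 1024,
    "toy_linear": 8,
}


@dataclass(frozen=True)
class EncoderSpec:
    """An encoder family and the channel width C of its final features."""

    family: str
    feature_channels: int | None = None

    def __post_init__(self):
        if self.family not in ENCODER_CHANNELS:
            raise ValueError(
                f"unknown encoder family {self.family!r}; "
                f"choose from {sorted(ENCODER_CHANNELS)}")
        expected = ENCODER_CHANNELS[self.family]
        if self.feature_channels is None:
            object.__setattr__(self, "feature_channels", expected)
        elif self.family != "toy_linear" and self.feature_channels != expected:
            raise ValueError(
                f"{self.family} has {expected} final feature channels, "
                f"got {self.feature_channels}")


# ---------------------------------------------------------------------------
# layer primitives (inference only)

class _Conv:
    def __init__(self, rng, cin, cout, k, stride=1, pad=None, groups=1,
                 bias=False):
        pad = k // 2 if pad is None else pad
        fan_in = cin // groups * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (cout, cin // groups, k, k))
        self.b = np.zeros(cout) if bias else None
        self.stride, self.pad, self.groups = stride, pad, groups

    def __call__(self, x):
        y, _ = conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad,
                      groups=self.groups)
        return y

    def arrays(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class _BN:
    def __init__(self, c):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.mean = np.zeros(c)     # running stats: not trainable
        self.var = np.ones(c)

    def __call__(self, x):
        scale = self.gamma / np.sqrt(self.var + 1e-5)
        shift = self.beta - self.mean * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    def arrays(self):
        return [self.gamma, self.beta]


def _relu6(x):
    return np.clip(x, 0.0, 6.0)


class _ConvBN:
    def __init__(self, rng, cin, cout, k, stride=1, groups=1, act="relu"):
        self.conv = _Conv(rng, cin, cout, k, stride=stride, groups=groups)
        self.bn = _BN(cout)
        self.act = act

    def __call__(self, x):
        y = self.bn(self.conv(x))
        if self.act == "relu":
            return relu(y)
        if self.act == "relu6":
            return _relu6(y)
        return y

    def arrays(self):
        return self.conv.arrays() + self.bn.arrays()


def _maxpool(x, k=3, stride=2, pad=1):
    n, c, h, w = x.shape
    cols = im2col(x.reshape(n * c, 1, h, w), k, k, stride, pad)
    return cols.max(axis=-1).reshape(n, c, *cols.shape[1:3])


# ---------------------------------------------------------------------------
# blocks

class _BasicBlock:
    def __init__(self, rng, cin, cout, stride):
        self.c1 = _ConvBN(rng, cin, cout, 3, stride=stride)
        self.c2 = _ConvBN(rng, cout, cout, 3, act=None)
        self.down = None
        if stride != 1 or cin != cout:
            self.down = _ConvBN(rng, cin, cout, 1, stride=stride, act=None)

    def __call__(self, x):
        idt = x if self.down is None else self.down(x)
        return relu(self.c2(self.c1(x)) + idt)

    def arrays(self):
        out = self.c1.arrays() + self.c2.arrays()
        if self.down is not None:
            out += self.down.arrays()
        return out


class _InvertedResidual:
    def __init__(self, rng, cin, cout, stride, expand):
        hidden = cin * expand
        self.use_res = stride == 1 and cin == cout
        self.layers = []
        if expand != 1:
            self.layers.append(_ConvBN(rng, cin, hidden, 1, act="relu6"))
        self.layers.append(_ConvBN(rng, hidden, hidden, 3, stride=stride,
                                   groups=hidden, act="relu6"))
        self.layers.append(_ConvBN(rng, hidden, cout, 1, act=None))

    def __call__(self, x):
        y = x
        for layer in self.layers:
            y = layer(y)
        return x + y if self.use_res else y

    def arrays(self):
        return [a for layer in self.layers for a in layer.arrays()]


def _channel_shuffle(x, groups=2):
    n, c, h, w = x.shape
    return (x.reshape(n, groups, c // groups, h, w)
            .transpose(0, 2, 1, 3, 4).reshape(n, c, h, w))


class _ShuffleUnit:
    def __init__(self, rng, cin, cout, stride):
        half = cout // 2
        self.stride = stride
        if stride == 1:
            self.branch1 = []
            b2_in = cin // 2
        else:
            self.branch1 = [
                _ConvBN(rng, cin, cin, 3, stride=2, groups=cin, act=None),
                _ConvBN(rng, cin, half, 1),
            ]
            b2_in = cin
        self.branch2 = [
            _ConvBN(rng, b2_in, half, 1),
            _ConvBN(rng, half, half, 3, stride=stride, groups=half, act=None),
            _ConvBN(rng, half, half, 1),
        ]

    def __call__(self, x):
        if self.stride == 1:
            c = x.shape[1] // 2
            x1, x2 = x[:, :c], x[:, c:]
        else:
            x1 = x2 = x
            for layer in self.branch1:
                x1 = layer(x1)
        for layer in self.branch2:
            x2 = layer(x2)
        return _channel_shuffle(np.concatenate([x1, x2], axis=1))

    def arrays(self):
        return [a for layer in self.branch1 + self.branch2
                for a in layer.arrays()]


# ---------------------------------------------------------------------------
# encoders

class _ConvEncoder:
    """Shared plumbing: a seeded stack of blocks + GAP, inference only."""

    MIN_INPUT = 32
    trainable = False

    def __init__(self, spec: EncoderSpec, seed: int):
        self.spec = spec
        self._build(np.random.default_rng(seed))

    @property
    def feature_channels(self) -> int:
        return self.spec.feature_channels

    def _check(self, image):
        if image.shape[0] < self.MIN_INPUT or image.shape[1] < self.MIN_INPUT:
            raise ValueError(
                f"image {image.shape[:2]} below encoder minimum "
                f"{self.MIN_INPUT}x{self.MIN_INPUT}")

    def features(self, image: np.ndarray) -> np.ndarray:
        """Final feature map (C, H', W') for one H x W x 3 image."""
        self._check(image)
        x = np.ascontiguousarray(
            image.transpose(2, 0, 1)[None], dtype=np.float64)
        return self._forward(x)[0]

    def pooled_features(self, image: np.ndarray) -> np.ndarray:
        f = self.features(image)
        return f.mean(axis=(1, 2))

    def trainable_arrays(self) -> list[np.ndarray]:
        return [a for block in self._blocks for a in block.arrays()]

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.trainable_arrays()))


class ResNetEncoder(_ConvEncoder):
    LAYERS = {"resnet18": (2, 2, 2, 2), "resnet34": (3, 4, 6, 3)}

    def _build(self, rng):
        blocks_per_stage = self.LAYERS[self.spec.family]
        self.stem = _ConvBN(rng, 3, 64, 7, stride=2)
        self.stages = []
        cin = 64
        for cout, n, stride in zip((64, 128, 256, 512), blocks_per_stage,
                                   (1, 2, 2, 2)):
            stage = []
            for i in range(n):
                stage.append(_BasicBlock(rng, cin, cout,
                                         stride if i == 0 else 1))
                cin = cout
            self.stages.append(stage)
        self._blocks = [self.stem] + [b for s in self.stages for b in s]

    def _forward(self, x):
        x = _maxpool(self.stem(x))
        for stage in self.stages:
            for block in stage:
                x = block(x)
        return x


class MobileNetV2Encoder(_ConvEncoder):
    # (expand t, out channels c, repeats n, first stride s)
    SETTINGS = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]

    def _build(self, rng):
        self.stem = _ConvBN(rng, 3, 32, 3, stride=2, act="relu6")
        self.body = []
        cin = 32
        for t, c, n, s in self.SETTINGS:
            for i in range(n):
                self.body.append(_InvertedResidual(rng, cin, c,
                                                   s if i == 0 else 1, t))
                cin = c
        self.head = _ConvBN(rng, cin, 1280, 1, act="relu6")
        self._blocks = [self.stem] + self.body + [self.head]

    def _forward(self, x):
        x = self.stem(x)
        for block in self.body:
            x = block(x)
        return self.head(x)


class ShuffleNetV2Encoder(_ConvEncoder):
    STAGES = [(116, 4), (232, 8), (464, 4)]     # 1.0x width

    def _build(self, rng):
        self.stem = _ConvBN(rng, 3, 24, 3, stride=2)
        self.units = []
        cin = 24
        for cout, n in self.STAGES:
            for i in range(n):
                self.units.append(_ShuffleUnit(rng, cin, cout,
                                               2 if i == 0 else 1))
                cin = cout
        self.head = _ConvBN(rng, cin, 1024, 1)
        self._blocks = [self.stem] + self.units + [self.head]

    def _forward(self, x):
        x = _maxpool(self.stem(x))
        for unit in self.units:
            x = unit(x)
        return self.head(x)


class ToyLinearEncoder:
    """Per-pixel linear map R^3 -> R^C followed by global average pooling.

    GAP of a per-pixel linear map equals the same map applied to the
    image's mean color, so the pooled feature is ``W @ mean_rgb + b`` —
    tiny, deterministic, and exactly differentiable by hand.  This is
    the encoder used for desk-scale transform training and unit tests.
    """

    MIN_INPUT = 1
    trainable = True

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        self.spec = spec
        c = spec.feature_channels
        rng = np.random.default_rng(seed)
        self.w = rng.normal(0.0, 0.5, (c, 3))
        self.b = np.zeros(c)

    @property
    def feature_channels(self) -> int:
        return self.spec.feature_channels

    def pooled_features(self, image: np.ndarray) -> np.ndarray:
        mean_rgb = np.asarray(image, dtype=np.float64).mean(axis=(0, 1))
        return self.w @ mean_rgb + self.b

    def pooled_features_batch(self, images) -> np.ndarray:
        means = np.stack([np.asarray(im).mean(axis=(0, 1)) for im in images])
        return means @ self.w.T + self.b

    def backward(self, mean_rgb: np.ndarray, dfp: np.ndarray):
        """Gradients for one sample given d(loss)/d(pooled feature)."""
        return {"w": np.outer(dfp, mean_rgb), "b": dfp}

    def trainable_arrays(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def n_parameters(self) -> int:
        return self.w.size + self.b.size


_FAMILIES = {
    "resnet18": ResNetEncoder,
    "resnet34": ResNetEncoder,
    "mobilenet_v2": MobileNetV2Encoder,
    "shufflenet_v2": ShuffleNetV2Encoder,
    "toy_linear": ToyLinearEncoder,
}


def build_encoder(spec: EncoderSpec | str, seed: int = 0):
    """Instantiate an encoder from a spec or family name, seeded."""
    if isinstance(spec, str):
        spec = EncoderSpec(family=spec)
    return _FAMILIES[spec.family](spec, seed)
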