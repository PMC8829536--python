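"""The dynamic color transform network: encoder -> GAP -> FC head.

The network maps an input image to the raw head output of one of the
two parameter formulations; the mappings in :mod:`.color_transform`
then turn that into a bounded ``(alpha, beta)`` pair.  The regression
head is a single fully-connected map from the pooled C-dimensional
feature to 2 pre-activations; the classification head maps to
``k_max + (2*j_max + 1)`` logits which are softmaxed per group.
"""

from __future__ import annotations

import io
import json

import numpy as np

from .color_transform import (
    ClassificationHeadConfig,
    HeadOutput,
    RegressionHeadConfig,
    TransformParams,
    as_rgb_image,
    classification_transform_params,
    regression_transform_params,
)
from .encoders import EncoderSpec, build_encoder

__all__ = [
    "DCTNetwork", "build_dct_network", "predict_params",
    "count_parameters", "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_VERSION = 1


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


class DCTNetwork:
    """Encoder + global-average-pooled feature + fully connected head."""

    def __init__(self, encoder, formulation: str, head_config, seed: int = 0):
        if formulation not in ("regression", "classification"):
            raise ValueError(f"unknown formulation {formulation!r}")
        expected = (RegressionHeadConfig if formulation == "regression"
                    else ClassificationHeadConfig)
        if not isinstance(head_config, expected):
            raise TypeError(
                f"{formulation} formulation needs a {expected.__name__}")
        self.encoder = encoder
        self.formulation = formulation
        self.head_config = head_config
        c = encoder.feature_channels
        rng = np.random.default_rng(seed)
        self.head_w = rng.normal(0.0, 0.01, (head_config.n_outputs, c))
        self.head_b = np.zeros(head_config.n_outputs)
        self.frozen = False

    # -- inference -------------------------------------------------------
    def head_output(self, image) -> HeadOutput:
        """Raw head output for one image."""
        image = as_rgb_image(image)
        fp = self.encoder.pooled_features(image)
        z = self.head_w @ fp + self.head_b
        return self._to_head_output(z)

    def _to_head_output(self, z: np.ndarray) -> HeadOutput:
        if self.formulation == "regression":
            return HeadOutput("regression",
                              alpha_preact=float(z[0]),
                              beta_preact=float(z[1]))
        k = self.head_config.n_alpha
        return HeadOutput("classification",
                          prob_alpha=_softmax(z[:k]),
                          prob_beta=_softmax(z[k:]))

    def predict(self, image) -> TransformParams:
        return predict_params(self, image)

    # -- training support (toy_linear encoder only) ----------------------
    @property
    def trainable(self) -> bool:
        return getattr(self.encoder, "trainable", False)

    def parameters(self) -> dict:
        params = {"head_w": self.head_w, "head_b": self.head_b}
        if self.trainable:
            params["enc_w"] = self.encoder.w
            params["enc_b"] = self.encoder.b
        return params

    def forward_train(self, image):
        """Forward pass caching what the hand-written backward needs."""
        if not self.trainable:
            raise RuntimeError(
                f"{self.encoder.spec.family} encoder does not support "
                "gradient training; use the toy_linear encoder")
        image = as_rgb_image(image)
        mean_rgb = image.mean(axis=(0, 1))
        fp = self.encoder.w @ mean_rgb + self.encoder.b
        z = self.head_w @ fp + self.head_b
        return z, (mean_rgb, fp)

    def backward_train(self, dz: np.ndarray, cache) -> dict:
        """Parameter gradients for one sample given d(loss)/d(logits)."""
        mean_rgb, fp = cache
        dfp = self.head_w.T @ dz
        return {
            "head_w": np.outer(dz, fp),
            "head_b": dz,
            "enc_w": np.outer(dfp, mean_rgb),
            "enc_b": dfp,
        }

    def n_parameters(self) -> int:
        head = self.head_w.size + self.head_b.size
        return self.encoder.n_parameters() + head


def build_dct_network(encoder: EncoderSpec | str,
                      formulation: str = "regression",
                      head_config=None, seed: int = 0) -> DCTNetwork:
    """Build a seeded DCT network.

    ``encoder`` may be a family name (``resnet18``, ``resnet34``,
    ``mobilenet_v2``, ``shufflenet_v2``, ``toy_linear``) or a full
    :class:`~dynacolor.encoders.EncoderSpec`.  ``head_config`` defaults
    to the standard hyperparameters of the chosen formulation.
    """
    if head_config is None:
        head_config = (RegressionHeadConfig() if formulation == "regression"
                       else ClassificationHeadConfig())
    enc = build_encoder(encoder, seed=seed)
    return DCTNetwork(enc, formulation, head_config, seed=seed)


def predict_params(network: DCTNetwork, image) -> TransformParams:
    """Image -> (alpha, beta) through the network and its formulation."""
    head = network.head_output(image)
    if network.formulation == "regression":
        return regression_transform_params(head, network.head_config)
    return classification_transform_params(head, network.head_config)


def count_parameters(network: DCTNetwork) -> int:
    """Number of trainable scalar weights, encoder and head included."""
    return network.n_parameters()


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(network: DCTNetwork, path) -> None:
    """Save weights + config to a single ``.npz`` archive (versioned)."""
    config = {
        "version": CHECKPOINT_VERSION,
        "family": network.encoder.spec.family,
        "feature_channels": network.encoder.feature_channels,
        "formulation": network.formulation,
        "head_config": vars(network.head_config).copy(),
    }
    arrays = {"head_w": network.head_w, "head_b": network.head_b}
    for i, a in enumerate(network.encoder.trainable_arrays()):
        arrays[f"enc_{i}"] = a
    np.savez_compressed(path, config=json.dumps(config), **arrays)


def load_checkpoint(path) -> DCTNetwork:
    with np.load(path, allow_pickle=False) as data:
        config = json.loads(str(data["config"]))
        if config["version"] != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {config['version']}")
        head_config = (RegressionHeadConfig(**config["head_config"])
                       if config["formulation"] == "regression"
                       else ClassificationHeadConfig(**config["head_config"]))
        spec = EncoderSpec(config["family"],
                           feature_channels=config["feature_channels"])
        net = DCTNetwork(build_encoder(spec), config["formulation"],
                         head_config)
        net.head_w = data["head_w"].copy()
        net.head_b = data["head_b"].copy()
        for i, a in enumerate(net.encoder.trainable_arrays()):
            a[...] = data[f"enc_{i}"]
    return net
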