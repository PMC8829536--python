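"""Linear color transform and its two parameter formulations.

The color model is a single global affine map applied identically to all
three channels of an RGB image normalized to [0, 1]::

    x' = alpha * x + beta

with a unified gain ``alpha`` and offset ``beta`` shared by R, G and B.
Two alternative parameterizations map raw network head outputs to
``(alpha, beta)``:

* **regression** — two unbounded pre-activations squashed into bounded
  open intervals, ``alpha = alpha_max * sigmoid(a_x)`` in
  ``(0, alpha_max)`` and ``beta = beta_max * (2/pi) * arctan(b_x)`` in
  ``(-beta_max, beta_max)``;
* **classification** — softmax probabilities over discrete value grids
  ``V_alpha = {i_alpha * k : k = 1..k_max}`` and
  ``V_beta = {i_beta * j : j = -j_max..j_max}``, combined by
  expectation.

Everything here is a pure in-memory mapping; no I/O, no learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormulationError",
    "TransformParams",
    "RegressionHeadConfig",
    "ClassificationHeadConfig",
    "HeadOutput",
    "as_rgb_image",
    "apply_color_transform",
    "regression_transform_params",
    "classification_transform_params",
    "build_alpha_values",
    "build_beta_values",
]


class FormulationError(ValueError):
    """A head output was fed to the mapping of the other formulation."""


def as_rgb_image(pixels) -> np.ndarray:
    """Validate and return an H x W x 3 float array of intensities.

    Accepts any array-like; raises ``ValueError`` on wrong channel count,
    empty spatial dimensions or non-finite values.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image has empty spatial extent: {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class TransformParams:
    """The (alpha, beta) pair of the global linear color transform."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("transform parameters must be finite")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    def compose(self, other: "TransformParams") -> "TransformParams":
        """Parameters equivalent to applying ``self`` then ``other``."""
        return TransformParams(
            alpha=other.alpha * self.alpha,
            beta=other.alpha * self.beta + other.beta,
        )


@dataclass(frozen=True)
class RegressionHeadConfig:
    """Value-range bounds of the regression formulation.

    Defaults give alpha in (0, 2) and beta in (-0.1, 0.1).
    """

    alpha_max: float = 2.0
    beta_max: float = 0.1

    def __post_init__(self):
        if self.alpha_max <= 0 or self.beta_max <= 0:
            raise ValueError("alpha_max and beta_max must be positive")

    @property
    def n_outputs(self) -> int:
        return 2


@dataclass(frozen=True)
class ClassificationHeadConfig:
    """Discrete value grids of the classification formulation.

    ``i_alpha``/``i_beta`` are step sizes; ``k_max`` levels span alpha in
    [i_alpha, i_alpha*k_max] and ``2*j_max + 1`` symmetric levels span
    beta in [-i_beta*j_max, i_beta*j_max].  Defaults give alpha levels
    {0.1, ..., 2.0} and beta levels {-0.2, -0.1, 0, 0.1, 0.2}.
    """

    i_alpha: float = 0.1
    k_max: int = 20
    i_beta: float = 0.1
    j_max: int = 2

    def __post_init__(self):
        if self.i_alpha <= 0 or self.i_beta <= 0:
            raise ValueError("step sizes must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.j_max < 0:
            raise ValueError("j_max must be >= 0")

    @property
    def n_alpha(self) -> int:
        return self.k_max

    @property
    def n_beta(self) -> int:
        return 2 * self.j_max + 1

    @property
    def n_outputs(self) -> int:
        return self.n_alpha + self.n_beta

    def alpha_values(self) -> np.ndarray:
        return build_alpha_values(self.i_alpha, self.k_max)

    def beta_values(self) -> np.ndarray:
        return build_beta_values(self.i_beta, self.j_max)


@dataclass(frozen=True)
class HeadOutput:
    """Raw output of a DCT network head, tagged by formulation.

    Regression carries two unbounded pre-activations; classification
    carries two probability vectors (each non-negative, summing to 1).
    """

    formulation: str
    alpha_preact: float | None = None
    beta_preact: float | None = None
    prob_alpha: np.ndarray | None = field(default=None)
    prob_beta: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.formulation == "regression":
            if self.alpha_preact is None or self.beta_preact is None:
                raise ValueError("regression head needs both pre-activations")
        elif self.formulation == "classification":
            for name, p in (("prob_alpha", self.prob_alpha),
                            ("prob_beta", self.prob_beta)):
                if p is None:
                    raise ValueError(f"classification head needs {name}")
                p = np.asarray(p, dtype=np.float64)
                if p.ndim != 1 or np.any(p < 0):
                    raise ValueError(f"{name} must be a non-negative vector")
                if abs(p.sum() - 1.0) > 1e-6:
                    raise ValueError(
                        f"{name} must sum to 1 (got {p.sum():.8f})"
                    )
                object.__setattr__(self, name, p)
        else:
            raise ValueError(f"unknown formulation {self.formulation!r}")


def apply_color_transform(image, params: TransformParams,
                          clip: bool = False) -> np.ndarray:
    """Apply ``x' = alpha * x + beta`` identically to all three channels.

    With ``clip`` the result is clamped to [0, 1] (use for export or
    visualization; leave off in training so the map stays linear).
    """
    arr = as_rgb_image(image)
    if not isinstance(params, TransformParams):
        params = TransformParams(*params)
    out = params.alpha * arr + params.beta
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def _sigmoid(x: float) -> float:
    # numerically safe for |x| up to inf
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def regression_transform_params(head: HeadOutput,
                                config: RegressionHeadConfig | None = None
                                ) -> TransformParams:
    """Map regression pre-activations to bounded (alpha, beta).

    alpha = alpha_max * sigmoid(alpha_preact)      in (0, alpha_max)
    beta  = beta_max * (2/pi) * arctan(beta_preact) in (-beta_max, beta_max)
    """
    if head.formulation != "regression":
        raise FormulationError(
            f"expected a regression head, got {head.formulation!r}"
        )
    if config is None:
        config = RegressionHeadConfig()
    alpha = config.alpha_max * _sigmoid(float(head.alpha_preact))
    # the sigmoid saturates in floating point for huge pre-activations;
    # keep alpha strictly inside the open interval (0, alpha_max)
    alpha = min(max(alpha, np.finfo(float).tiny),
                np.nextafter(config.alpha_max, 0.0))
    beta = config.beta_max * (2.0 / np.pi) * np.arctan(float(head.beta_preact))
    return TransformParams(alpha=float(alpha), beta=float(beta))


def build_alpha_values(i_alpha: float, k_max: int) -> np.ndarray:
    """Discrete gain levels ``{i_alpha * k : k = 1..k_max}``."""
    if i_alpha <= 0:
        raise ValueError("i_alpha must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return i_alpha * np.arange(1, k_max + 1, dtype=np.float64)


def build_beta_values(i_beta: float, j_max: int) -> np.ndarray:
    """Discrete offset levels ``{i_beta * j : j = -j_max..j_max}``.

    Odd-symmetric about 0 and always containing 0; length 2*j_max + 1.
    """
    if i_beta <= 0:
        raise ValueError("i_beta must be positive")
    if j_max < 0:
        raise ValueError("j_max must be >= 0")
    return i_beta * np.arange(-j_max, j_max + 1, dtype=np.float64)


def classification_transform_params(head: HeadOutput,
                                    config: ClassificationHeadConfig | None = None
                                    ) -> TransformParams:
    """Expected (alpha, beta) under the head's discrete distributions."""
    if head.formulation != "classification":
        raise FormulationError(
            f"expected a classification head, got {head.formulation!r}"
        )
    if config is None:
        config = ClassificationHeadConfig()
    v_alpha = config.alpha_values()
    v_beta = config.beta_values()
    if head.prob_alpha.shape[0] != v_alpha.shape[0]:
        raise ValueError(
            f"prob_alpha has length {head.prob_alpha.shape[0]}, "
            f"config defines {v_alpha.shape[0]} alpha levels"
        )
    if head.prob_beta.shape[0] != v_beta.shape[0]:
        raise ValueError(
            f"prob_beta has length {head.prob_beta.shape[0]}, "
            f"config defines {v_beta.shape[0]} beta levels"
        )
    alpha = float(np.dot(v_alpha, head.prob_alpha))
    beta = float(np.dot(v_beta, head.prob_beta))
    return TransformParams(alpha=alpha, beta=beta)
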