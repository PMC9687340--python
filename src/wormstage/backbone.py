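"""Compound-scaled convolutional feature extractor with an attention block.

The M1 path: a stem convolution, a stack of depthwise-separable
convolution blocks (depthwise 3x3 + pointwise 1x1, each followed by
feature normalization and ReLU), an optional attention block, and global
average pooling (GAP) producing the deep feature vector ``F1``.

**Compound scaling.** Depth, width and input resolution scale jointly as
``d = d0 * alpha**phi``, ``w = w0 * beta**phi``, ``r = r0 * gamma**phi``.
The published bases are ``alpha = 2.3``, ``beta = 1.5``, ``gamma = 1.18``;
note that these do not satisfy the usual FLOPs constraint
``alpha * beta**2 * gamma**2 ~= 2`` (the product is ~7.2). The scaler
accepts them as given and reports the constraint value rather than
altering them — see :func:`compound_scale`.

**Attention.** The final feature map ``F`` is passed through three 1x1
convolutions with feature normalization and ReLU/ReLU/Sigmoid activations,
yielding an attention map ``A`` in [0, 1] with the same shape as ``F``.
The attention output is the per-channel ratio ``O = GAP(A) / GAP(A * F)``
(the denominator epsilon-guarded), applied as a multiplicative gate on the
pooled features: ``F1 = O * GAP(F)``. With attention disabled,
``F1 = GAP(F)`` exactly.

The extractor is forward-only: weights are drawn once from a seeded
truncated normal (He-scaled, which keeps activation magnitudes stable
through the stack) and fixed, making it a deterministic random-projection
feature bank; supervised fitting happens downstream in the fusion head.
Channel normalization is applied at the feature level — the pooled F1
vector is standardized with training-set statistics before fusion — rather
than per layer: per-layer, per-image normalization would discard the
global activation magnitude, which carries most of the aggregation signal
(spot count and density). Inside the attention block the 1x1 convolution
outputs are standardized spatially so the sigmoid operates in a sensible
range.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

logger = logging.getLogger(__name__)

EPS = 1e-7


@dataclass(frozen=True)
class ScalingConfig:
    """Compound-scaling bases and the desk-scale base architecture."""

    phi: float = 0.0
    alpha: float = 2.3
    beta: float = 1.5
    gamma: float = 1.18
    base_depth: int = 4  # depthwise-separable blocks after the stem
    base_width: int = 32  # channels of the widest stage
    base_resolution: int = 128

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1 or self.gamma < 1:
            raise ValueError("scaling bases alpha, beta, gamma must be >= 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


@dataclass(frozen=True)
class ConstraintReport:
    """Value of ``alpha * beta**2 * gamma**2`` and whether it is ~2."""

    value: float
    satisfied: bool
    tolerance: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "within" if self.satisfied else "VIOLATES"
        return (
            f"alpha*beta^2*gamma^2 = {self.value:.4g} {status} "
            f"~2 (tolerance {self.tolerance})"
        )


@dataclass(frozen=True)
class ScaledDims:
    depth: int
    width: int
    resolution: int
    multipliers: tuple[float, float, float]


def compound_scale(
    config: ScalingConfig, phi: float | None = None, tolerance: float = 0.25
) -> tuple[ScaledDims, ConstraintReport]:
    """Scale depth/width/resolution by ``alpha**phi, beta**phi, gamma**phi``.

    Depth rounds up; width rounds to the nearest multiple of 8 (at least
    8); resolution rounds to the nearest integer. The report carries the
    FLOPs-constraint value ``alpha * beta**2 * gamma**2`` with a flag —
    the published bases give ~7.2, which violates the nominal ~2 target,
    and that violation is reported, not repaired.
    """
    phi = config.phi if phi is None else phi
    if phi < 0:
        raise ValueError("phi must be >= 0")
    d_mult = config.alpha**phi
    w_mult = config.beta**phi
    r_mult = config.gamma**phi
    depth = int(math.ceil(config.base_depth * d_mult))
    width = max(8, int(round(config.base_width * w_mult / 8)) * 8)
    resolution = int(round(config.base_resolution * r_mult))
    constraint = config.alpha * config.beta**2 * config.gamma**2
    report = ConstraintReport(
        value=constraint,
        satisfied=abs(constraint - 2.0) <= tolerance,
        tolerance=tolerance,
    )
    return ScaledDims(depth, width, resolution, (d_mult, w_mult, r_mult)), report


@dataclass(frozen=True)
class StageSpec:
    kind: str  # "stem" | "dwsep"
    in_channels: int
    out_channels: int
    stride: int


@dataclass(frozen=True)
class BackboneSpec:
    stages: tuple[StageSpec, ...]
    input_resolution: int
    feature_channels: int
    attention_enabled: bool = True
    attention_position: int = -1  # after the last conv stage
    seed: int = 0

    @property
    def feature_length(self) -> int:
        return self.feature_channels


def _truncated_normal(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float
) -> np.ndarray:
    draw = rng.standard_normal(shape)
    # redraw the tails: |z| <= 2
    out_of_range = np.abs(draw) > 2
    while out_of_range.any():
        draw[out_of_range] = rng.standard_normal(int(out_of_range.sum()))
        out_of_range = np.abs(draw) > 2
    return draw * sd


def build_backbone(
    scaling: ScalingConfig | None = None,
    desk_scale: bool = True,
    attention_enabled: bool = True,
    seed: int = 0,
) -> tuple[BackboneSpec, dict[str, np.ndarray]]:
    """Construct the stage layout and seeded weights.

    The layout is stem (3x3, stride 2) followed by ``depth``
    depthwise-separable blocks; blocks at positions 1 and 3 use stride 2,
    and channel width doubles (capped at the scaled width) halfway through.
    ``desk_scale=False`` quadruples base width and depth for larger runs.
    """
    scaling = scaling or ScalingConfig()
    if not desk_scale:
        scaling = ScalingConfig(
            phi=scaling.phi,
            alpha=scaling.alpha,
            beta=scaling.beta,
            gamma=scaling.gamma,
            base_depth=scaling.base_depth * 4,
            base_width=scaling.base_width * 4,
            base_resolution=scaling.base_resolution * 2,
        )
    dims, report = compound_scale(scaling)
    if not report.satisfied:
        logger.info("compound-scaling constraint: %s", report)

    stem_ch = max(8, dims.width // 2)
    stages = [StageSpec("stem", 1, stem_ch, stride=2)]
    ch = stem_ch
    for i in range(dims.depth):
        out_ch = dims.width if i >= dims.depth // 2 else stem_ch
        stride = 2 if i in (1, dims.depth - 1) and i > 0 else 1
        stages.append(StageSpec("dwsep", ch, out_ch, stride))
        ch = out_ch

    spec = BackboneSpec(
        stages=tuple(stages),
        input_resolution=dims.resolution,
        feature_channels=ch,
        attention_enabled=attention_enabled,
        seed=seed,
    )
    return spec, init_weights(spec)


def init_weights(spec: BackboneSpec) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    weights: dict[str, np.ndarray] = {}
    for i, st in enumerate(spec.stages):
        if st.kind == "stem":
            fan_in = st.in_channels * 9
            weights[f"stage{i}.conv"] = _truncated_normal(
                rng, (st.out_channels, st.in_channels, 3, 3), math.sqrt(2 / fan_in)
            )
        else:
            weights[f"stage{i}.dw"] = _truncated_normal(
                rng, (st.in_channels, 3, 3), math.sqrt(2 / 9)
            )
            weights[f"stage{i}.pw"] = _truncated_normal(
                rng, (st.out_channels, st.in_channels), math.sqrt(2 / st.in_channels)
            )
    c = spec.feature_channels
    mid = max(8, c // 2)
    weights["att.conv1"] = _truncated_normal(rng, (mid, c), math.sqrt(2 / c))
    weights["att.conv2"] = _truncated_normal(rng, (mid, mid), math.sqrt(2 / mid))
    weights["att.conv3"] = _truncated_normal(rng, (c, mid), math.sqrt(2 / mid))
    return weights


def _normalize(x: np.ndarray) -> np.ndarray:
    """Per-channel standardization by the map's own spatial statistics."""
    mean = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    return (x - mean) / (sd + EPS)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _conv3x3(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Full 3x3 convolution, reflect padding. x: CxHxW, w: OxCx3x3."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    out = np.tensordot(w, windows, axes=([1, 2, 3], [0, 3, 4]))
    return out[:, ::stride, ::stride]


def _depthwise3x3(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Depthwise 3x3 convolution. x: CxHxW, w: Cx3x3."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    out = np.einsum("chwij,cij->chw", windows, w)
    return out[:, ::stride, ::stride]


def _pointwise(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """1x1 convolution. x: CxHxW, w: OxC."""
    return np.tensordot(w, x, axes=([1], [0]))


def gap(x: np.ndarray) -> np.ndarray:
    """Global average pooling over spatial dims: CxHxW -> C."""
    return x.mean(axis=(1, 2))


def attention_forward(
    feature_map: np.ndarray, weights: dict[str, np.ndarray], eps: float = EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Attention map ``A`` and per-channel output ``O = GAP(A)/GAP(A*F)``.

    ``A = sigmoid(n(conv3(relu(n(conv2(relu(n(conv1(F)))))))))`` where the
    convs are 1x1 and ``n`` is feature normalization. The division is
    per channel; denominators smaller than ``eps`` in magnitude are
    epsilon-stabilized and the event is logged.
    """
    if not np.all(np.isfinite(feature_map)):
        raise ValueError("non-finite feature map")
    h = _relu(_normalize(_pointwise(feature_map, weights["att.conv1"])))
    h = _relu(_normalize(_pointwise(h, weights["att.conv2"])))
    attention_map = _sigmoid(_normalize(_pointwise(h, weights["att.conv3"])))

    numerator = gap(attention_map)
    denominator = gap(attention_map * feature_map)
    small = np.abs(denominator) < eps
    if small.any():
        logger.debug("attention denominator eps-stabilized on %d channels", small.sum())
        denominator = np.where(small, np.where(denominator < 0, -eps, eps), denominator)
    return attention_map, numerator / denominator


def backbone_forward(
    image: np.ndarray, spec: BackboneSpec, weights: dict[str, np.ndarray]
) -> np.ndarray:
    """Run the full M1 path on one pooled grayscale image, returning F1.

    The image is resized (with a warning) if it does not match the spec's
    input resolution. F1 has length ``spec.feature_channels``; with
    attention enabled it is the attention-gated GAP of the final feature
    map, otherwise the plain GAP.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    r = spec.input_resolution
    if image.shape != (r, r):
        warnings.warn(
            f"input {image.shape} resized to backbone resolution {r}x{r}",
            stacklevel=2,
        )
        image = sktransform.resize(image, (r, r), anti_aliasing=True)

    x = image[None, :, :]
    for i, st in enumerate(spec.stages):
        if st.kind == "stem":
            x = _relu(_conv3x3(x, weights[f"stage{i}.conv"], st.stride))
        else:
            x = _relu(_depthwise3x3(x, weights[f"stage{i}.dw"], st.stride))
            x = _relu(_pointwise(x, weights[f"stage{i}.pw"]))

    pooled = gap(x)
    if spec.attention_enabled:
        _, gate = attention_forward(x, weights)
        return gate * pooled
    return pooled


def count_parameters(weights: dict[str, np.ndarray]) -> int:
    return int(sum(w.size for w in weights.values()))


class AttentionBackbone:
    """Convenience wrapper tying a spec to its weights."""

    def __init__(
        self,
        scaling: ScalingConfig | None = None,
        desk_scale: bool = True,
        attention_enabled: bool = True,
        seed: int = 0,
    ) -> None:
        self.spec, self.weights = build_backbone(
            scaling, desk_scale=desk_scale, attention_enabled=attention_enabled, seed=seed
        )

    @property
    def feature_length(self) -> int:
        return self.spec.feature_length

    def forward(self, image: np.ndarray) -> np.ndarray:
        return backbone_forward(image, self.spec, self.weights)
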