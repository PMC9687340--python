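"""Aggregation feature vector F2 from sorted pairwise spot distances.

The degree of protein aggregation is summarized by the smallest pairwise
center distances between detected spots: for N spots there are
``N*(N-1)/2`` Euclidean distances; sorted ascending, the first ``n``
(default 12) form the feature vector, and missing entries are padded with a
sentinel value of 5000 px (an upper bound on any realistic spot distance at
the instrument's resolution). Tightly clustered spots therefore produce
elementwise-smaller vectors than dispersed ones, and images with fewer than
two spots produce the all-sentinel vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from wormstage.preprocessing import FilterConfig, preprocess_for_detection
from wormstage.spot_detector import BlobParams, SpotSet, detect_spots

DEFAULT_N = 12
DEFAULT_PAD = 5000.0


@dataclass(frozen=True)
class DistanceSet:
    """All pairwise Euclidean center distances of a spot set, in pixels."""

    values: np.ndarray

    @property
    def m(self) -> int:
        return len(self.values)


def pairwise_distances(spots: SpotSet) -> DistanceSet:
    """Euclidean distances between all unordered pairs of spot centers;
    empty for fewer than two spots."""
    centers = spots.centers()
    if len(centers) < 2:
        return DistanceSet(values=np.empty(0, dtype=float))
    return DistanceSet(values=pdist(centers))


def build_feature_vector(
    distances: DistanceSet, n: int = DEFAULT_N, pad_value: float = DEFAULT_PAD
) -> np.ndarray:
    """Sort distances ascending, clip at ``pad_value``, keep the first
    ``n``, and pad the remainder with ``pad_value``.

    Clipping before selection keeps the sentinel an upper bound even when
    the image diagonal exceeds it, and preserves the non-decreasing order
    of the output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pad_value <= 0:
        raise ValueError("pad_value must be > 0")
    sorted_clipped = np.minimum(np.sort(distances.values), pad_value)
    out = np.full(n, pad_value, dtype=float)
    k = min(len(sorted_clipped), n)
    out[:k] = sorted_clipped[:k]
    return out


def extract_f2(
    image: np.ndarray,
    blob_params: BlobParams | None = None,
    filter_config: FilterConfig | None = None,
    n: int = DEFAULT_N,
    pad_value: float = DEFAULT_PAD,
    image_id: str = "",
) -> np.ndarray:
    """Full M2 path on a raw image: preprocess -> detect spots -> pairwise
    distances -> fixed-length sorted/padded vector. Deterministic."""
    conditioned = preprocess_for_detection(image, filter_config or FilterConfig())
    spots = detect_spots(conditioned, blob_params or BlobParams(), image_id=image_id)
    return build_feature_vector(pairwise_distances(spots), n=n, pad_value=pad_value)


class FeatureStandardizer:
    """Per-dimension z-scoring of F2, fit on the training set.

    Raw distances are O(10^2–10^3) px while CNN features are O(1); without
    standardization the fused feature vector would be scale-dominated by
    the distances. Constant dimensions (e.g. all-sentinel padding slots)
    get unit scale to avoid division by zero.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, features: np.ndarray) -> "FeatureStandardizer":
        features = np.asarray(features, dtype=float)
        self.mean_ = features.mean(axis=0)
        scale = features.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean_ is None or self.scale_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(features, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, features: np.ndarray) -> np.ndarray:
        return self.fit(features).transform(features)
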