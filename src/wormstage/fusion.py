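"""Dual-path fusion and the lifespan-stage softmax classifier.

The deep feature vector ``F1`` (M1 path) and the aggregation vector ``F2``
(M2 path) are each standardized with training-set statistics, concatenated,
and fed to a small dense head — Dense(hidden) + ReLU + dropout +
Dense(k) + softmax — trained with categorical cross-entropy, Adam updates
and early stopping on a validation split carved from the training data.

The three experimental arms (M1-only, M2-only, M1+M2) share every code
path; an arm simply masks out the columns of the other path before the
head. Disabling both paths is rejected.

Everything here is implemented directly on numpy arrays with explicit
gradients, so runs are exactly reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from wormstage.aggregation_features import (
    DEFAULT_N,
    DEFAULT_PAD,
    FeatureStandardizer,
    extract_f2,
)
from wormstage.backbone import AttentionBackbone, ScalingConfig
from wormstage.preprocessing import FilterConfig, downsample_average_pool
from wormstage.spot_detector import BlobParams

N_CLASSES = 6
LOG_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 10
    dropout_rate: float = 0.5
    hidden_units: int = 128
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.early_stop_patience < self.max_epochs:
            raise ValueError("need 0 < early_stop_patience < max_epochs")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis (max-subtraction)."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean categorical cross-entropy; ``y_true`` one-hot, ``y_pred`` rows
    are probability vectors. Logs are clipped at 1e-12."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    return float(-(y_true * np.log(np.clip(y_pred, LOG_EPS, None))).sum(axis=1).mean())


def one_hot(labels: np.ndarray, k: int = N_CLASSES) -> np.ndarray:
    """Labels in 1..k to one-hot rows."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels outside [1, {k}]")
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


class DenseHead:
    """Two-layer dense softmax classifier with inverted dropout."""

    def __init__(self, in_dim: int, hidden: int, k: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.w1 = rng.standard_normal((in_dim, hidden)) * np.sqrt(2.0 / in_dim)
        self.b1 = np.zeros(hidden)
        self.w2 = rng.standard_normal((hidden, k)) * np.sqrt(2.0 / hidden)
        self.b2 = np.zeros(k)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.w1, self.b1 = params["w1"].copy(), params["b1"].copy()
        self.w2, self.b2 = params["w2"].copy(), params["b2"].copy()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        return softmax(h @ self.w2 + self.b2)

    def _forward_train(
        self, x: np.ndarray, dropout_rate: float, rng: np.random.Generator
    ) -> tuple[np.ndarray, tuple]:
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        if dropout_rate > 0:
            keep = 1.0 - dropout_rate
            mask = (rng.random(h.shape) < keep) / keep
            h_dropped = h * mask
        else:
            mask = None
            h_dropped = h
        probs = softmax(h_dropped @ self.w2 + self.b2)
        return probs, (x, h, mask, h_dropped)

    def _gradients(
        self, probs: np.ndarray, y: np.ndarray, cache: tuple
    ) -> dict[str, np.ndarray]:
        x, h, mask, h_dropped = cache
        n = len(x)
        dlogits = (probs - y) / n
        grads = {
            "w2": h_dropped.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dh = dlogits @ self.w2.T
        if mask is not None:
            dh = dh * mask
        dh = dh * (h > 0)
        grads["w1"] = x.T @ dh
        grads["b1"] = dh.sum(axis=0)
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _stratified_val_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def train_head(
    head: DenseHead,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> pd.DataFrame:
    """Optimize the head in place; returns the per-epoch history
    (train_loss, val_loss, val_acc). Stops once the validation loss has
    failed to improve for ``early_stop_patience`` consecutive epochs and
    restores the best-validation weights."""
    rng = np.random.default_rng(config.seed)
    params = head.params
    optimizer = _Adam(params, config.learning_rate)
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad_epochs = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            probs, cache = head._forward_train(
                x_train[batch], config.dropout_rate, rng
            )
            loss = cross_entropy_loss(y_train[batch], probs)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss {loss}) at epoch {epoch}"
                )
            grads = head._gradients(probs, y_train[batch], cache)
            optimizer.step(params, grads)
            epoch_losses.append(loss)
        val_probs = head.predict_proba(x_val)
        val_loss = cross_entropy_loss(y_val, val_probs)
        val_acc = float(
            (val_probs.argmax(axis=1) == y_val.argmax(axis=1)).mean()
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                break
    head.set_params(best_params)
    return pd.DataFrame(rows)


@dataclass
class StageModel:
    """The full dual-path model: backbone + F2 standardizer + fusion head.

    ``use_m1`` / ``use_m2`` select the experimental arm; the fused input is
    built by masking the disabled path's columns so all arms share one code
    path.
    """

    use_m1: bool = True
    use_m2: bool = True
    backbone_seed: int = 0
    attention_enabled: bool = True
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    blob_params: BlobParams = field(default_factory=BlobParams)
    f2_dim: int = DEFAULT_N
    pad_value: float = DEFAULT_PAD

    def __post_init__(self) -> None:
        if not (self.use_m1 or self.use_m2):
            raise ValueError("at least one of the M1/M2 paths must be enabled")
        self.backbone = AttentionBackbone(
            scaling=self.scaling,
            attention_enabled=self.attention_enabled,
            seed=self.backbone_seed,
        )
        self.f1_standardizer = FeatureStandardizer()
        self.f2_standardizer = FeatureStandardizer()
        self.head: DenseHead | None = None
        self.history: pd.DataFrame | None = None

    # ---- feature extraction -------------------------------------------------

    def compute_f1(self, image: np.ndarray) -> np.ndarray:
        pooled = downsample_average_pool(image, self.filter_config.pool_factor)
        return self.backbone.forward(pooled)

    def compute_f2(self, image: np.ndarray) -> np.ndarray:
        return extract_f2(
            image,
            blob_params=self.blob_params,
            filter_config=self.filter_config,
            n=self.f2_dim,
            pad_value=self.pad_value,
        )

    def compute_features(
        self, images: Sequence[np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Raw (unstandardized) F1 and F2 matrices for a list of images."""
        f1 = np.stack([self.compute_f1(im) for im in images])
        f2 = np.stack([self.compute_f2(im) for im in images])
        return f1, f2

    def _fuse(self, f1: np.ndarray, f2: np.ndarray, fit: bool = False) -> np.ndarray:
        f1 = np.atleast_2d(f1)
        f2 = np.atleast_2d(f2)
        if fit:
            self.f1_standardizer.fit(f1)
            self.f2_standardizer.fit(f2)
        z1 = self.f1_standardizer.transform(f1)
        z2 = self.f2_standardizer.transform(f2)
        if not self.use_m1:
            z1 = np.zeros_like(z1)
        if not self.use_m2:
            z2 = np.zeros_like(z2)
        return np.concatenate([z1, z2], axis=1)

    # ---- training / inference ----------------------------------------------

    def fit_features(
        self,
        f1: np.ndarray,
        f2: np.ndarray,
        labels: np.ndarray,
        config: TrainConfig | None = None,
    ) -> pd.DataFrame:
        """Train the fusion head on precomputed raw features; returns the
        training history."""
        config = config or TrainConfig()
        labels = np.asarray(labels, dtype=int)
        fused = self._fuse(f1, f2, fit=True)
        y = one_hot(labels)
        rng = np.random.default_rng(config.seed)
        tr, va = _stratified_val_split(labels, config.val_fraction, rng)
        if len(va) == 0:
            raise ValueError("validation split is empty; need >= 2 samples per class")
        self.head = DenseHead(
            fused.shape[1], config.hidden_units, N_CLASSES, seed=config.seed
        )
        self.history = train_head(
            self.head, fused[tr], y[tr], fused[va], y[va], config
        )
        return self.history

    def fit(
        self,
        images: Sequence[np.ndarray],
        labels: np.ndarray,
        config: TrainConfig | None = None,
    ) -> pd.DataFrame:
        f1, f2 = self.compute_features(images)
        return self.fit_features(f1, f2, labels, config)

    def predict_proba_features(self, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise RuntimeError("model is not trained")
        return self.head.predict_proba(self._fuse(f1, f2))

    def predict_stage(self, image: np.ndarray) -> tuple[np.ndarray, int]:
        """Full dual-path inference on one raw image: returns the 6-class
        probability vector and the hard group label in 1..6."""
        f1 = self.compute_f1(image)
        f2 = self.compute_f2(image)
        probs = self.predict_proba_features(f1[None, :], f2[None, :])[0]
        return probs, int(probs.argmax()) + 1

    # ---- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if self.head is None:
            raise RuntimeError("nothing to save: model is not trained")
        meta = {
            "use_m1": self.use_m1,
            "use_m2": self.use_m2,
            "backbone_seed": self.backbone_seed,
            "attention_enabled": self.attention_enabled,
            "scaling": asdict(self.scaling),
            "filter_config": asdict(self.filter_config),
            "blob_params": asdict(self.blob_params),
            "f2_dim": self.f2_dim,
            "pad_value": self.pad_value,
        }
        arrays = {
            "f1_mean": self.f1_standardizer.mean_,
            "f1_scale": self.f1_standardizer.scale_,
            "f2_mean": self.f2_standardizer.mean_,
            "f2_scale": self.f2_standardizer.scale_,
            **{f"head_{k}": v for k, v in self.head.params.items()},
        }
        with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
            np.savez(fh, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "StageModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            model = cls(
                use_m1=meta["use_m1"],
                use_m2=meta["use_m2"],
                backbone_seed=meta["backbone_seed"],
                attention_enabled=meta["attention_enabled"],
                scaling=ScalingConfig(**meta["scaling"]),
                filter_config=FilterConfig(**meta["filter_config"]),
                blob_params=BlobParams(**meta["blob_params"]),
                f2_dim=meta["f2_dim"],
                pad_value=meta["pad_value"],
            )
            model.f1_standardizer.mean_ = archive["f1_mean"]
            model.f1_standardizer.scale_ = archive["f1_scale"]
            model.f2_standardizer.mean_ = archive["f2_mean"]
            model.f2_standardizer.scale_ = archive["f2_scale"]
            head = DenseHead(
                archive["head_w1"].shape[0], archive["head_w1"].shape[1], N_CLASSES, 0
            )
            head.set_params(
                {k: archive[f"head_{k}"] for k in ("w1", "b1", "w2", "b2")}
            )
            model.head = head
        return model


def softmax_predict(x: np.ndarray, head: DenseHead) -> np.ndarray:
    """Probability vector for a single fused feature vector."""
    return head.predict_proba(x)[0]
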