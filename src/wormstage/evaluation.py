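"""Evaluation: confusion matrices, accuracy/recall/precision/F1, the
three-arm ablation protocol, and feature-only classical baselines.

Metrics follow the one-vs-rest reduction: for each class, TP/FP/FN/TN are
counted against all other classes pooled, giving per-class

* ``AC = (TP + TN) / (TP + TN + FP + FN)``
* ``Recall = TP / (TP + FN)``
* ``P = TP / (TP + FP)``
* ``F1 = 2 P R / (P + R)``

Headline Recall/P/F1 figures are macro-averages over classes with nonzero
support (classes without support are reported as NaN and excluded, with a
log note). The headline overall accuracy is ``trace / total`` — the plain
fraction of correctly classified samples — reported alongside the mean
per-class one-vs-rest AC, which is a different quantity in the multiclass
setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from wormstage import staging
from wormstage.fusion import N_CLASSES, StageModel, TrainConfig
from wormstage.synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows are true classes, columns predicted."""

    counts: np.ndarray

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``cls`` in 1..k."""
        i = cls - 1
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(y_true, y_pred, k: int = N_CLASSES) -> ConfusionMatrix:
    """Tally the confusion matrix for labels in 1..k."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("no samples")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.min() < 1 or arr.max() > k:
            raise ValueError(f"{name} labels outside [1, {k}]")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts=counts)


@dataclass(frozen=True)
class MetricReport:
    """Per-class and aggregate classification metrics."""

    per_class: pd.DataFrame  # columns: class, support, AC, Recall, P, F1
    macro: dict[str, float]  # macro-averaged AC, Recall, P, F1
    overall_accuracy: float  # trace / total
    averaging: str = "macro (zero-support classes excluded)"


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Per-class one-vs-rest metrics plus macro averages and trace/total
    overall accuracy. Degenerate ``P + R = 0`` gives F1 = 0 (flagged in the
    log); zero-support classes report NaN and are excluded from macros."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for cls in range(1, cm.k + 1):
        tp, fp, fn, tn = cm.one_vs_rest(cls)
        support = tp + fn
        if support == 0:
            logger.info("class %d has zero support; excluded from macro averages", cls)
            rows.append(
                dict(klass=cls, support=0, AC=np.nan, Recall=np.nan, P=np.nan, F1=np.nan)
            )
            continue
        ac = (tp + tn) / cm.total
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            logger.info("class %d: P + R = 0, F1 reported as 0", cls)
            f1 = 0.0
        rows.append(
            dict(klass=cls, support=support, AC=ac, Recall=recall, P=precision, F1=f1)
        )
    per_class = pd.DataFrame(rows).rename(columns={"klass": "class"})
    valid = per_class.dropna(subset=["AC"])
    macro = {
        name: float(valid[name].mean()) for name in ("AC", "Recall", "P", "F1")
    }
    overall = float(np.trace(cm.counts) / cm.total)
    return MetricReport(per_class=per_class, macro=macro, overall_accuracy=overall)


ARMS = ("M1", "M2", "M1+M2")


def _arm_model(arm: str, template: StageModel) -> StageModel:
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    return replace(
        template, use_m1=arm in ("M1", "M1+M2"), use_m2=arm in ("M2", "M1+M2")
    )


def run_ablation(
    cohort: Cohort,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    model_template: StageModel | None = None,
    include_baselines: bool = False,
) -> tuple[pd.DataFrame, dict[str, ConfusionMatrix]]:
    """Train and evaluate the M1-only, M2-only and M1+M2 arms.

    All arms share the same stratified 80/20 split, the same seed, and the
    same precomputed raw features (the arms differ only in which path's
    columns are masked before the fusion head), so the comparison isolates
    the contribution of each path. Returns a table with one row per arm
    (overall accuracy, macro Recall, macro F1) and the per-arm confusion
    matrices. With ``include_baselines`` the classical F2-only baselines
    (random forest, SVM) are evaluated on the identical split and appended.
    """
    train_config = train_config or TrainConfig(seed=seed)
    template = model_template or StageModel(backbone_seed=seed)

    manifest = cohort.manifest.copy()
    manifest["_row"] = np.arange(len(manifest))
    train_m, test_m = staging.split_dataset(manifest, seed=seed)
    tr = train_m["_row"].to_numpy()
    te = test_m["_row"].to_numpy()
    labels = manifest["stage_group"].to_numpy()
    images = [im.pixels for im in cohort.images]
    if len(images) != len(manifest):
        raise ValueError("cohort images and manifest rows disagree")

    # features are arm-independent; compute once on the fused template
    base = _arm_model("M1+M2", template)
    f1_all, f2_all = base.compute_features(images)

    rows = []
    matrices: dict[str, ConfusionMatrix] = {}
    for arm in ARMS:
        model = _arm_model(arm, template)
        model.fit_features(f1_all[tr], f2_all[tr], labels[tr], train_config)
        probs = model.predict_proba_features(f1_all[te], f2_all[te])
        predicted = probs.argmax(axis=1) + 1
        cm = confusion(labels[te], predicted)
        report = metrics(cm)
        matrices[arm] = cm
        rows.append(
            {
                "model": arm,
                "AC": report.overall_accuracy,
                "Recall": report.macro["Recall"],
                "F1": report.macro["F1"],
            }
        )

    if include_baselines:
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        scaler = StandardScaler().fit(f2_all[tr])
        for name, clf in (
            ("random_forest (F2 only)", RandomForestClassifier(random_state=seed)),
            ("svm (F2 only)", SVC(random_state=seed)),
        ):
            clf.fit(scaler.transform(f2_all[tr]), labels[tr])
            predicted = clf.predict(scaler.transform(f2_all[te]))
            cm = confusion(labels[te], predicted)
            report = metrics(cm)
            matrices[name] = cm
            rows.append(
                {
                    "model": name,
                    "AC": report.overall_accuracy,
                    "Recall": report.macro["Recall"],
                    "F1": report.macro["F1"],
                }
            )
    return pd.DataFrame(rows), matrices


def run_feature_baselines(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> dict[str, MetricReport]:
    """Classical baselines on aggregation features only.

    Fits a random forest and an RBF support vector machine (scikit-learn
    defaults, fixed seed) on standardized F2 vectors — no image content —
    with a stratified train/test split, and reports per-class AC/Recall/F1
    plus overall accuracy for each.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")

    x_tr, x_te, y_tr, y_te = train_test_split(
        features,
        labels,
        test_size=test_fraction,
        random_state=seed,
        stratify=labels,
    )
    scaler = StandardScaler().fit(x_tr)
    x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)

    models = {
        "random_forest": RandomForestClassifier(random_state=seed),
        "svm": SVC(random_state=seed),
    }
    reports: dict[str, MetricReport] = {}
    for name, model in models.items():
        model.fit(x_tr, y_tr)
        predicted = model.predict(x_te)
        reports[name] = metrics(confusion(y_te, predicted))
    return reports
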