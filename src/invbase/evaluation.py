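"""Classifier evaluation: stratified k-fold and leave-one-subject-out.

Three fixed classifier configurations are supported: an MLP with hidden
layers (64, 32), an RBF-kernel SVM, and a kd-tree kNN with five
neighbours.  Features are z-scored inside each training fold by default
(the classifiers are scale-sensitive and band magnitudes span orders of
magnitude); the scaler never sees test data.  Accuracy is the fraction
of correct predictions; F1 is the harmonic mean of precision and recall
with the "high" class as positive (macro-averaged for multiclass
targets).

Leave-one-subject-out (LOSO) holds out every record of one subject per
fold and is the operational test of subject independence: a method whose
features still encode subject identity collapses toward chance here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigurationError, ValidationError
from .features import FeatureRecord

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "make_classifier",
    "records_to_arrays",
    "compute_metrics",
    "run_kfold",
    "run_loso",
]

POSITIVE_LABEL = "high"


@dataclass
class ClassifierConfig:
    """Fixed classifier hyper-parameters.

    kind: "mlp" (hidden layers 64 and 32), "svm" (RBF kernel) or "knn"
    (kd-tree, 5 neighbours).  ``standardize`` toggles the in-fold
    z-scoring; ``seed`` fixes fold shuffling and MLP initialisation.
    """

    kind: str = "mlp"
    mlp_hidden: tuple[int, int] = (64, 32)
    mlp_max_iter: int = 400
    svm_kernel: str = "rbf"
    knn_neighbors: int = 5
    knn_algorithm: str = "kd_tree"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "svm", "knn"):
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")


def make_classifier(cfg: ClassifierConfig):
    """Build the sklearn estimator (optionally wrapped in a scaler pipeline)."""
    if cfg.kind == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=cfg.mlp_hidden,
            max_iter=cfg.mlp_max_iter,
            random_state=cfg.seed,
        )
    elif cfg.kind == "svm":
        est = SVC(kernel=cfg.svm_kernel, random_state=cfg.seed)
    else:
        est = KNeighborsClassifier(
            n_neighbors=cfg.knn_neighbors, algorithm=cfg.knn_algorithm
        )
    if cfg.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class EvalReport:
    """Per-fold (or per-subject) accuracies and F1 scores with their means."""

    target: str
    protocol: str
    unit_ids: list[str]
    per_unit_accuracy: list[float]
    per_unit_f1: list[float]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.per_unit_accuracy + self.per_unit_f1:
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"metric {v} outside [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_unit_accuracy))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.per_unit_f1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.unit_ids,
                "accuracy": self.per_unit_accuracy,
                "f1": self.per_unit_f1,
            }
        )

    def summary(self) -> dict:
        return {
            "target": self.target,
            "protocol": self.protocol,
            "n_units": len(self.unit_ids),
            "mean_accuracy": self.mean_accuracy,
            "mean_f1": self.mean_f1,
            "config": self.config,
        }

    def save(self, csv_path, json_path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        with open(json_path, "w") as f:
            json.dump(self.summary(), f, indent=2, sort_keys=True)


def records_to_arrays(
    records: list[FeatureRecord], target: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack records into (X, y, subject) arrays for the given target axis."""
    if target not in ("valence", "arousal"):
        raise ValidationError(f"unknown target {target!r}")
    X = np.vstack([r.features for r in records])
    attr = "valence_label" if target == "valence" else "arousal_label"
    y = np.array([getattr(r, attr) for r in records])
    subjects = np.array([r.subject_id for r in records])
    return X, y, subjects


def compute_metrics(
    y_true, y_pred, positive: str = POSITIVE_LABEL
) -> tuple[float, float]:
    """Accuracy and F1 for one evaluation unit.

    Binary targets use ``positive`` as the positive class and the
    P+R = 0 case yields F1 = 0; more than two classes fall back to
    macro-averaged F1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, non-empty")
    acc = accuracy_score(y_true, y_pred)
    labels = set(y_true) | set(y_pred)
    if labels <= {positive} or len(labels) <= 2:
        f1 = f1_score(y_true, y_pred, pos_label=positive, zero_division=0)
    else:
        f1 = f1_score(y_true, y_pred, average="macro", zero_division=0)
    return float(acc), float(f1)


def _config_snapshot(clf: ClassifierConfig, protocol: str, **extra) -> dict:
    snap = asdict(clf)
    snap["protocol"] = protocol
    snap.update(extra)
    return snap


def run_kfold(
    records: list[FeatureRecord],
    target: str,
    clf: ClassifierConfig,
    k: int = 10,
) -> EvalReport:
    """Stratified k-fold cross-validation at the record (window) level."""
    X, y, _ = records_to_arrays(records, target)
    if len(records) < k:
        raise ValidationError(f"k={k} exceeds the {len(records)} records")
    if len(set(y)) < 2:
        raise ValidationError("both classes must be present for stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=clf.seed)
    accs, f1s, units = [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(set(y[tr])) < 2:
            raise ValidationError(f"fold {fold}: training split has one class")
        est = make_classifier(clf)
        est.fit(X[tr], y[tr])
        acc, f1 = compute_metrics(y[te], est.predict(X[te]))
        accs.append(acc)
        f1s.append(f1)
        units.append(f"fold{fold}")
    return EvalReport(
        target=target,
        protocol="kfold",
        unit_ids=units,
        per_unit_accuracy=accs,
        per_unit_f1=f1s,
        config=_config_snapshot(clf, "kfold", k=k),
    )


def run_loso(
    records: list[FeatureRecord], target: str, clf: ClassifierConfig
) -> EvalReport:
    """Leave-one-subject-out: one evaluation unit per held-out subject."""
    X, y, subjects = records_to_arrays(records, target)
    order = list(dict.fromkeys(subjects))  # first-appearance order
    if len(order) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    accs, f1s, units = [], [], []
    for subj in order:
        te = subjects == subj
        tr = ~te
        if len(set(y[tr])) < 2:
            raise ValidationError(
                f"training split holding out {subj!r} has a single class"
            )
        est = make_classifier(clf)
        est.fit(X[tr], y[tr])
        acc, f1 = compute_metrics(y[te], est.predict(X[te]))
        accs.append(acc)
        f1s.append(f1)
        units.append(subj)
    return EvalReport(
        target=target,
        protocol="loso",
        unit_ids=units,
        per_unit_accuracy=accs,
        per_unit_f1=f1s,
        config=_config_snapshot(clf, "loso"),
    )
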