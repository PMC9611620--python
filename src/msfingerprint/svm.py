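"""Group-aware repeated splitting, linear SVM training, and evaluation.

Samples are split 70/30 at the specimen level, so technical replicates and
augmented descendants of one plant-part extract always land on the same side
of the boundary (no leakage).  A one-vs-rest linear SVM is trained on the
unfolded tensor; its per-class weight vectors feed the marker miner.  Repeated
random splits give mean +/- SD precision/recall/F1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.svm import LinearSVC

from .core import DatasetTensor
from .gridding import FeatureIndexMap, unfold


@dataclass(frozen=True)
class SplitPlan:
    """Repeated grouped 70/30 split: groups (specimens) never straddle sets.

    With ``stratify`` the 70/30 partition is drawn within each class, so
    every class keeps specimens on both sides even at very small specimen
    counts (otherwise groups are drawn from the pooled list, as in a plain
    random extract split).
    """

    train_fraction: float = 0.7
    n_repeats: int = 3
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def split_group_keys(
    group_keys, plan: SplitPlan, repeat: int = 0, group_classes: dict | None = None
) -> set:
    """Choose the training groups for one repeat, deterministically."""
    keys = sorted(set(group_keys))
    if len(keys) < 2:
        raise ValueError("need at least 2 specimen groups to split")
    rng = np.random.default_rng([plan.seed, repeat])
    if plan.stratify and group_classes is not None:
        strata = {}
        for k in keys:
            strata.setdefault(group_classes[k], []).append(k)
    else:
        strata = {None: keys}
    train: set = set()
    for _, stratum in sorted(strata.items(), key=lambda kv: str(kv[0])):
        order = rng.permutation(len(stratum))
        n_train = int(round(plan.train_fraction * len(stratum)))
        n_train = min(max(n_train, 1), len(stratum) - 1) if len(stratum) > 1 else 1
        train.update(stratum[i] for i in order[:n_train])
    return train


def grouped_split(
    tensor: DatasetTensor, plan: SplitPlan, repeat: int = 0
) -> tuple[list[str], list[str]]:
    """Partition sample_ids ~70/30 by specimen group, deterministically.

    Augmented variants inherit their parent's specimen_id, so they always
    travel with the parent.
    """
    groups = [s.group_id for s in tensor]
    group_classes = {s.group_id: s.label for s in tensor}
    train_keys = split_group_keys(groups, plan, repeat, group_classes)
    train_ids, test_ids = [], []
    for s in tensor:
        (train_ids if s.group_id in train_keys else test_ids).append(s.sample_id)
    return train_ids, test_ids


@dataclass
class SvmModel:
    """One-vs-rest linear SVM with per-class weight vectors exposed."""

    estimator: LinearSVC
    classes: list[str]
    index_map: FeatureIndexMap | None = None

    def coef(self, label: str) -> np.ndarray:
        """Weight vector of one class over the unfolded feature space."""
        if label not in self.classes:
            raise KeyError(f"unknown class {label!r}; have {self.classes}")
        return self.estimator.coef_[self.classes.index(label)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def train_svm(
    X: np.ndarray,
    y,
    class_weighting: bool = True,
    C: float = 1.0,
    index_map: FeatureIndexMap | None = None,
    max_iter: int = 200,
    dual: bool = False,
) -> SvmModel:
    """Fit a linear one-vs-rest SVM on an unfolded matrix.

    Raw intensities are used as-is (no scaling); ``class_weighting`` applies
    balanced class weights against class imbalance.  The primal solver
    (``dual=False``) conditions far better on raw-intensity scales than the
    dual one and optimizes the same squared-hinge objective.
    """
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train")
    est = LinearSVC(
        C=C,
        class_weight="balanced" if class_weighting else None,
        dual=dual,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*max_iter.*")
        est.fit(X, y)
    if len(classes) == 2 and est.coef_.shape[0] == 1:
        # expose one weight vector per class also in the binary case
        est.coef_ = np.vstack([-est.coef_[0], est.coef_[0]])
    return SvmModel(estimator=est, classes=[str(c) for c in est.classes_],
                    index_map=index_map)


def evaluate(model: SvmModel, X_test: np.ndarray, y_test) -> dict:
    """Per-class and macro precision/recall/F1 (plus accuracy) on a test set."""
    return score_predictions(np.asarray(y_test), model.predict(X_test), model.classes)


def score_predictions(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> dict:
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and predictions")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=np.nan
    )
    per_class = {}
    for i, c in enumerate(classes):
        if support[i] == 0:
            warnings.warn(f"class {c!r} has no test samples; metrics undefined")
        per_class[c] = {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro = {
            "precision": float(np.nanmean(prec)),
            "recall": float(np.nanmean(rec)),
            "f1": float(np.nanmean(f1)),
        }
    return {
        "per_class": per_class,
        "macro": macro,
        "accuracy": float(accuracy_score(y_true, y_pred)),
    }


@dataclass
class ClassificationReport:
    """Per-repeat metrics with mean +/- SD aggregation."""

    classes: list[str]
    repeats: list[dict] = field(default_factory=list)

    def add(self, repeat_metrics: dict) -> None:
        self.repeats.append(repeat_metrics)

    def _collect(self, getter) -> np.ndarray:
        return np.array([getter(r) for r in self.repeats], dtype=np.float64)

    def macro(self, metric: str) -> tuple[float, float]:
        """(mean, SD) of a macro metric over repeats; SD=0 for one repeat."""
        v = self._collect(lambda r: r["macro"][metric])
        return float(np.nanmean(v)), float(np.nanstd(v))

    def per_class(self, label: str, metric: str) -> tuple[float, float]:
        v = self._collect(lambda r: r["per_class"][label][metric])
        return float(np.nanmean(v)), float(np.nanstd(v))

    @property
    def accuracy(self) -> tuple[float, float]:
        v = self._collect(lambda r: r["accuracy"])
        return float(np.nanmean(v)), float(np.nanstd(v))

    def summary(self) -> str:
        lines = [f"{'':10s} {'precision':>16s} {'recall':>16s} {'f1':>16s}"]
        for c in self.classes:
            cells = [
                "%.2f ± %.2f" % self.per_class(c, m)
                for m in ("precision", "recall", "f1")
            ]
            lines.append(f"{c:10s} {cells[0]:>16s} {cells[1]:>16s} {cells[2]:>16s}")
        cells = ["%.2f ± %.2f" % self.macro(m) for m in ("precision", "recall", "f1")]
        lines.append(f"{'macro':10s} {cells[0]:>16s} {cells[1]:>16s} {cells[2]:>16s}")
        lines.append("accuracy   %.2f ± %.2f  (%d repeats)" % (*self.accuracy, len(self.repeats)))
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "classes": self.classes,
            "repeats": self.repeats,
            "aggregate": {
                "macro": {
                    m: dict(zip(("mean", "sd"), self.macro(m)))
                    for m in ("precision", "recall", "f1")
                },
                "per_class": {
                    c: {
                        m: dict(zip(("mean", "sd"), self.per_class(c, m)))
                        for m in ("precision", "recall", "f1")
                    }
                    for c in self.classes
                },
                "accuracy": dict(zip(("mean", "sd"), self.accuracy)),
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def cross_validate_matrix(
    X: np.ndarray,
    y,
    groups,
    plan: SplitPlan | None = None,
    class_weighting: bool = True,
    C: float = 1.0,
) -> ClassificationReport:
    """Repeated grouped-split SVM training/evaluation on an unfolded matrix.

    ``groups`` holds one specimen key per row; rows sharing a key never
    straddle the train/test boundary.  This matrix-level entry point lets
    callers drop the heatmap tensor before fitting, which matters for
    augmented datasets.
    """
    plan = plan or SplitPlan()
    y = np.asarray(y)
    groups = np.asarray(groups)
    if not (len(X) == len(y) == len(groups)):
        raise ValueError("X, y and groups must have equal length")
    classes = sorted(set(y.tolist()))
    group_classes = {g: c for g, c in zip(groups.tolist(), y.tolist())}
    report = ClassificationReport(classes=classes)
    for repeat in range(plan.n_repeats):
        train_keys = split_group_keys(groups, plan, repeat, group_classes)
        tr = np.isin(groups, sorted(train_keys))
        model = train_svm(X[tr], y[tr], class_weighting=class_weighting, C=C)
        # score against the full vocabulary: a class missing from this
        # repeat's training set still counts (recall 0) on the test side
        report.add(score_predictions(y[~tr], model.predict(X[~tr]), classes))
    return report


def cross_validate(
    tensor: DatasetTensor,
    plan: SplitPlan | None = None,
    class_weighting: bool = True,
    C: float = 1.0,
    dtype=None,
) -> ClassificationReport:
    """Repeated grouped-split training and evaluation of the linear SVM."""
    X, _ = unfold(tensor, dtype=dtype)
    groups = [s.group_id for s in tensor]
    return cross_validate_matrix(
        X, tensor.labels, groups, plan, class_weighting=class_weighting, C=C
    )
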