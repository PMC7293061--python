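"""Class-weighted classification and incremental feature-subset evaluation.

The outcome classes are heavily imbalanced (about 15% positive), so the
minority class receives extra weight in the training objective -- a 4:1
minority:majority ratio by default.  Performance is estimated by k-fold
cross-validation (k=5, stratified by default) reporting accuracy, sensitivity
and specificity, and the classifier is re-trained after adding each feature
in rank order to trace how performance grows with the feature subset
("incremental curve").  The declared best subset size maximizes
min(sensitivity, specificity), ties broken toward fewer features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .datasets import POSITIVE
from .infotheory import RankingResult, jmim_rank
from .preprocessing import EncodedMatrix, encode_features

__all__ = [
    "ClassifierSpec",
    "FoldAssignment",
    "ConfusionCounts",
    "MetricSet",
    "PerformanceCurve",
    "make_folds",
    "make_classifier",
    "fit_predict",
    "compute_metrics",
    "confusion_from_predictions",
    "incremental_curve",
    "run_variant",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to train and how to weight the minority class."""

    family: str = "svm"  # {"svm", "random_forest"}
    class_weight_ratio: float = 4.0  # minority:majority
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("svm", "random_forest"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if not self.class_weight_ratio > 0:
            raise ValueError("class_weight_ratio must be > 0")


@dataclass(frozen=True)
class FoldAssignment:
    """Per-patient fold index in 1..k (every index appears; folds non-empty)."""

    fold_index: np.ndarray
    k: int
    strategy: str
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def make_folds(labels, k: int = 5, strategy: str = "stratified", seed: int = 0) -> FoldAssignment:
    """Partition samples into k cross-validation folds.

    ``stratified`` keeps class proportions per fold (each fold's positive
    count within 1 of the expected share); ``random`` splits uniformly, which
    with few positives can leave a fold with almost none.
    """
    y = np.asarray(labels)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if strategy == "stratified":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y)
    elif strategy == "random":
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    else:
        raise ValueError(f"unknown fold strategy {strategy!r}")
    fold_index = np.zeros(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splits, start=1):
        fold_index[test_idx] = fold
    return FoldAssignment(fold_index, k, strategy, seed)


def make_classifier(spec: ClassifierSpec, y_train):
    """Configured sklearn estimator with minority-class weighting.

    The minority class of the training labels gets ``class_weight_ratio``
    times the weight of the majority class.
    """
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            "training fold contains a single class; use stratified folds")
    minority = classes[np.argmin(counts)]
    weights = {cls: (spec.class_weight_ratio if cls == minority else 1.0) for cls in classes}
    if spec.family == "svm":
        params = {"kernel": "rbf", "C": 1.0, "gamma": "scale", **spec.hyperparameters}
        return SVC(class_weight=weights, random_state=spec.seed, **params)
    params = {"n_estimators": 500, **spec.hyperparameters}
    return RandomForestClassifier(class_weight=weights, random_state=spec.seed, **params)


def fit_predict(spec: ClassifierSpec, X_train, y_train, X_test) -> np.ndarray:
    """Train on the training slice and predict labels for the test slice."""
    clf = make_classifier(spec, y_train)
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return clf.predict(np.asarray(X_test, dtype=float))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive = abnormal stress echo."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true) == POSITIVE
    p = np.asarray(y_pred) == POSITIVE
    return ConfusionCounts(
        tp=int((t & p).sum()), fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()), fp=int((~t & p).sum()))


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity, specificity (with across-fold standard errors)."""

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_se: float = 0.0
    sensitivity_se: float = 0.0
    specificity_se: float = 0.0

    def __post_init__(self):
        for v in (self.accuracy, self.sensitivity, self.specificity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")
        for v in (self.accuracy_se, self.sensitivity_se, self.specificity_se):
            if v < 0:
                raise ValueError("standard errors must be nonnegative")


def compute_metrics(confusion: ConfusionCounts) -> MetricSet:
    """Point metrics from one confusion table.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total.  Requires at least one sample of each class.
    """
    if confusion.tp + confusion.fn < 1:
        raise ValueError("no positive samples in the test set")
    if confusion.tn + confusion.fp < 1:
        raise ValueError("no negative samples in the test set")
    return MetricSet(
        accuracy=(confusion.tp + confusion.tn) / confusion.total,
        sensitivity=confusion.tp / (confusion.tp + confusion.fn),
        specificity=confusion.tn / (confusion.tn + confusion.fp),
    )


@dataclass
class CurvePoint:
    k: int
    feature_added: str
    fold_averaged: MetricSet
    pooled: MetricSet
    fold_confusions: list[ConfusionCounts] = field(default_factory=list)


@dataclass
class PerformanceCurve:
    """Cross-validated metrics for each top-k feature subset."""

    points: list[CurvePoint]
    best_k: int

    def __post_init__(self):
        if not self.points:
            raise ValueError("curve must have at least one point")
        if not 1 <= self.best_k <= len(self.points):
            raise ValueError("best_k out of range")

    def point(self, k: int) -> CurvePoint:
        return self.points[k - 1]

    def to_csv(self, path_or_buf=None, header_comment: str | None = None):
        rows = ["k,feature_added,accuracy,acc_se,sensitivity,sens_se,specificity,spec_se,"
                "pooled_accuracy,pooled_sensitivity,pooled_specificity"]
        for pt in self.points:
            m, q = pt.fold_averaged, pt.pooled
            rows.append(
                f"{pt.k},{pt.feature_added},{m.accuracy:.6f},{m.accuracy_se:.6f},"
                f"{m.sensitivity:.6f},{m.sensitivity_se:.6f},"
                f"{m.specificity:.6f},{m.specificity_se:.6f},"
                f"{q.accuracy:.6f},{q.sensitivity:.6f},{q.specificity:.6f}")
        text = "\n".join(rows) + "\n"
        if header_comment:
            text = "".join(f"# {line}\n" for line in header_comment.splitlines()) + text
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)


def _fold_mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), se


def incremental_curve(
    matrix: EncodedMatrix,
    ranking: RankingResult,
    spec: ClassifierSpec,
    folds: FoldAssignment,
) -> PerformanceCurve:
    """Cross-validated performance after adding each feature in rank order.

    For each k the classifier is trained and tested on the top-k ranked
    features over every fold rotation; per-fold metrics are averaged (their
    spread gives the standard error) and the pooled-confusion metrics are
    kept alongside for consistency checks.
    """
    missing = set(matrix.feature_names) - set(ranking.features)
    if missing:
        raise ValueError(f"ranking does not cover features: {sorted(missing)}")
    y = np.asarray(matrix.y)
    points = []
    for k in range(1, len(ranking.features) + 1):
        feats = ranking.top(k)
        X = matrix.X[feats].to_numpy(dtype=float)
        per_fold, confusions = {"accuracy": [], "sensitivity": [], "specificity": []}, []
        for fold in range(1, folds.k + 1):
            tr, te = folds.train_indices(fold), folds.test_indices(fold)
            pred = fit_predict(spec, X[tr], y[tr], X[te])
            cm = confusion_from_predictions(y[te], pred)
            m = compute_metrics(cm)
            confusions.append(cm)
            per_fold["accuracy"].append(m.accuracy)
            per_fold["sensitivity"].append(m.sensitivity)
            per_fold["specificity"].append(m.specificity)
        acc, acc_se = _fold_mean_se(per_fold["accuracy"])
        sens, sens_se = _fold_mean_se(per_fold["sensitivity"])
        spc, spc_se = _fold_mean_se(per_fold["specificity"])
        pooled = compute_metrics(sum(confusions[1:], confusions[0]))
        points.append(CurvePoint(
            k=k, feature_added=feats[-1],
            fold_averaged=MetricSet(acc, sens, spc, acc_se, sens_se, spc_se),
            pooled=pooled, fold_confusions=confusions))

    trade_off = [min(pt.fold_averaged.sensitivity, pt.fold_averaged.specificity)
                 for pt in points]
    best_k = int(np.argmax(trade_off)) + 1  # argmax takes the first max: fewer features
    return PerformanceCurve(points, best_k)


def run_variant(
    cohort: pd.DataFrame,
    variant: str = "full",
    classifier: ClassifierSpec | None = None,
    k_folds: int = 5,
    fold_strategy: str = "stratified",
    seed: int = 0,
    n_bins: int = 10,
) -> tuple[RankingResult, PerformanceCurve]:
    """End-to-end pipeline for one cohort variant.

    ``full`` uses every row and feature; ``no_prior_cad`` drops the patients
    with a prior CAD diagnosis and the prior-CAD column; ``no_sex`` keeps all
    rows but drops the sex column.  The cohort is encoded, features are ranked
    by JMIM on the whole dataset, and the incremental cross-validated curve is
    computed.
    """
    if variant == "full":
        sub = cohort
    elif variant == "no_prior_cad":
        if "prior_cad" not in cohort.columns:
            raise ValueError("variant no_prior_cad needs a prior_cad column")
        sub = cohort.loc[cohort["prior_cad"] == 0].drop(columns=["prior_cad"])
        sub = sub.reset_index(drop=True)
    elif variant == "no_sex":
        sex_cols = [c for c in cohort.columns if c.startswith("sex")]
        if not sex_cols:
            raise ValueError("variant no_sex needs a sex column")
        sub = cohort.drop(columns=sex_cols)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    matrix = encode_features(sub, n_bins=n_bins)
    ranking = jmim_rank(matrix)
    spec = classifier if classifier is not None else ClassifierSpec(seed=seed)
    if classifier is None:
        spec = replace(spec, seed=seed)
    folds = make_folds(matrix.y, k=k_folds, strategy=fold_strategy, seed=seed)
    curve = incremental_curve(matrix, ranking, spec, folds)
    return ranking, curve
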