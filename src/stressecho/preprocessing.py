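"""Normalization, equal-width discretization, and categorical encoding.

Continuous variables (age, weight) are min-max normalized to [0, 1] and then
cut into 10 equal-width bins indexed 1..10; binary variables pass through as
0/1 and smoking is coded nonsmoker=0, ex-smoker=1, smoker=2.  The result is
the fully discrete patient-by-feature matrix that the mutual-information
feature-selection stage requires.

Bins are left-closed, right-open, with the final bin right-closed so the
observed maximum lands in bin ``n_bins``; values outside the fitted range
clamp to the end bins.  A constant feature has width 0 and maps everywhere to
bin 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import OUTCOME_COLUMN, SMOKING_LABELS

__all__ = [
    "DiscretizationModel",
    "EncodedMatrix",
    "EqualWidthDiscretizer",
    "CohortEncoder",
    "min_max_normalize",
    "fit_discretizer",
    "apply_discretizer",
    "encode_features",
]

logger = logging.getLogger(__name__)

SMOKING_CODES = {label: code for code, label in enumerate(SMOKING_LABELS)}


def min_max_normalize(values) -> np.ndarray:
    """Map values to [0, 1] via (x - min) / (max - min).

    A constant vector maps to all zeros.  Empty or non-finite input raises
    ``ValueError``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass
class DiscretizationModel:
    """Fitted equal-width binning for one continuous feature."""

    feature: str
    observed_min: float
    observed_max: float
    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.observed_max < self.observed_min:
            raise ValueError("max must be >= min")

    @property
    def bin_width(self) -> float:
        return (self.observed_max - self.observed_min) / self.n_bins

    def transform(self, values) -> np.ndarray:
        """Bin indices in 1..n_bins; out-of-range values clamp to the ends."""
        x = np.asarray(values, dtype=float)
        if self.bin_width == 0.0:
            return np.ones(x.shape, dtype=int)
        raw = np.floor((x - self.observed_min) / self.bin_width).astype(int) + 1
        return np.clip(raw, 1, self.n_bins)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "feature": self.feature,
                "observed_min": float(self.observed_min),
                "observed_max": float(self.observed_max),
                "n_bins": int(self.n_bins),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "DiscretizationModel":
        doc = yaml.safe_load(text)
        return cls(doc["feature"], doc["observed_min"], doc["observed_max"], doc["n_bins"])


def fit_discretizer(values, n_bins: int = 10, feature: str = "feature") -> DiscretizationModel:
    """Fit an equal-width discretizer on a continuous vector."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit on an empty vector")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    model = DiscretizationModel(feature, float(x.min()), float(x.max()), n_bins)
    if model.bin_width == 0.0:
        logger.warning("feature %r is constant; all values map to bin 1", feature)
    return model


def apply_discretizer(model: DiscretizationModel, values) -> np.ndarray:
    return model.transform(values)


class EqualWidthDiscretizer(TransformerMixin, BaseEstimator):
    """sklearn transformer: per-column equal-width binning into 1..n_bins.

    Stores one :class:`DiscretizationModel` per column in ``models_``.
    """

    def __init__(self, n_bins: int = 10):
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            X = X.reshape(-1, 1)
        self.n_features_in_ = X.shape[1]
        self.models_ = [
            fit_discretizer(X[:, j], self.n_bins, feature=f"x{j}")
            for j in range(X.shape[1])
        ]
        return self

    def transform(self, X):
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            X = X.reshape(-1, 1)
        return np.column_stack([m.transform(X[:, j]) for j, m in enumerate(self.models_)])


@dataclass
class EncodedMatrix:
    """Discrete patient-by-feature matrix with its parallel label vector."""

    X: pd.DataFrame  # small nonnegative integer codes
    y: np.ndarray    # "positive"/"negative" per row

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ValueError("row count must equal label count")
        if self.X.isna().any().any():
            raise ValueError("encoded matrix contains missing entries")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def select(self, features) -> "EncodedMatrix":
        return EncodedMatrix(self.X[list(features)].copy(), self.y)

    def to_csv(self, path_or_buf, header_comment: str | None = None) -> None:
        out = self.X.copy()
        out[OUTCOME_COLUMN] = self.y
        text = out.to_csv(index=False)
        if header_comment:
            text = "".join(f"# {line}\n" for line in header_comment.splitlines()) + text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "EncodedMatrix":
        table = pd.read_csv(path_or_buf, comment="#")
        y = table.pop(OUTCOME_COLUMN).to_numpy(dtype=object)
        return cls(table.astype(int), y)


class CohortEncoder(TransformerMixin, BaseEstimator):
    """Encode a cohort table into the discrete matrix the selector needs.

    Binary columns pass through as 0/1; smoking is ordinally coded
    (nonsmoker=0, ex-smoker=1, smoker=2); continuous columns are min-max
    normalized and equal-width discretized into 1..n_bins.  The discretizer is
    fitted on the full column before any fold split (whole-dataset
    preprocessing); refit per training fold for leakage-free estimates.
    """

    def __init__(self, n_bins: int = 10, continuous: tuple[str, ...] = ("age", "weight")):
        self.n_bins = n_bins
        self.continuous = continuous

    def fit(self, cohort: pd.DataFrame, y=None):
        self.discretizers_ = {}
        for col in self.continuous:
            if col in cohort.columns:
                normalized = min_max_normalize(cohort[col].to_numpy(dtype=float))
                self.discretizers_[col] = fit_discretizer(normalized, self.n_bins, feature=col)
                # transform needs the original min/max to re-normalize new data
                self.ranges_ = getattr(self, "ranges_", {})
                x = cohort[col].to_numpy(dtype=float)
                self.ranges_[col] = (float(x.min()), float(x.max()))
        return self

    def transform(self, cohort: pd.DataFrame) -> EncodedMatrix:
        check_is_fitted(self, "discretizers_")
        encoded = {}
        for col in cohort.columns:
            if col == OUTCOME_COLUMN:
                continue
            if col in self.discretizers_:
                lo, hi = self.ranges_[col]
                x = cohort[col].to_numpy(dtype=float)
                normalized = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
                encoded[col] = self.discretizers_[col].transform(normalized)
            elif col == "smoking":
                codes = cohort[col].map(SMOKING_CODES)
                if codes.isna().any():
                    row = int(codes.index[codes.isna()][0])
                    raise ValueError(
                        f"unknown category {cohort[col].iloc[row]!r} in column 'smoking', row {row}")
                encoded[col] = codes.to_numpy(dtype=int)
            else:
                vals = cohort[col].to_numpy()
                bad = ~np.isin(vals, (0, 1))
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise ValueError(
                        f"unknown value {vals[row]!r} in binary column {col!r}, row {row}")
                encoded[col] = vals.astype(int)
        X = pd.DataFrame(encoded, columns=[c for c in cohort.columns if c != OUTCOME_COLUMN])
        if OUTCOME_COLUMN not in cohort.columns:
            raise ValueError("cohort is missing the outcome column")
        return EncodedMatrix(X, cohort[OUTCOME_COLUMN].to_numpy(dtype=object))

    def fit_transform(self, cohort: pd.DataFrame, y=None) -> EncodedMatrix:
        return self.fit(cohort).transform(cohort)


def encode_features(cohort: pd.DataFrame, n_bins: int = 10) -> EncodedMatrix:
    """Whole-dataset encoding: fit the encoder on ``cohort`` and transform it."""
    return CohortEncoder(n_bins=n_bins).fit_transform(cohort)
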