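"""Discriminant-analysis classification of recombination histories.

Feature vectors extracted by n-tuple subsampling are assigned to
recombination-history models with Gaussian discriminant analysis: LDA
(pooled covariance) or QDA (per-class covariances), both with uniform
priors since the simulation designs are balanced.  Accuracy is measured by
jackknife (leave-one-out) cross-validation: each dataset is classified by
a discriminant fitted on all the others, and the assignment rate is the
fraction reassigned to the model that generated them.

Features are standardized, and missing entries imputed with the feature
mean, *inside each training fold only* (no leakage into the held-out row).
Ties between discriminant scores are broken deterministically by the
declared label order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.impute import SimpleImputer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "THREE_MODEL_LABELS",
    "FOUR_MODEL_LABELS",
    "DiscriminantModel",
    "AccuracyReport",
    "fit_lda",
    "fit_qda",
    "predict",
    "loocv_accuracy",
]

log = logging.getLogger(__name__)

THREE_MODEL_LABELS = ("constant", "linear-inc", "linear-dec")
FOUR_MODEL_LABELS = ("constant-low", "constant-high", "linear-inc", "linear-dec")


@dataclass
class DiscriminantModel:
    """A fitted LDA/QDA pipeline with its label order and feature schema."""

    pipeline: Pipeline
    labels: tuple
    feature_names: tuple
    method: str


@dataclass
class AccuracyReport:
    """Confusion matrix (rows: true, columns: assigned) and assignment rates."""

    confusion: pd.DataFrame
    per_class: dict
    overall: float
    feature_names: tuple
    method: str = "lda"

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "per_class": self.per_class,
            "confusion": self.confusion.to_dict(),
            "features": list(self.feature_names),
            "method": self.method,
        }


def _label_order(y: Sequence[str], labels: Optional[Sequence[str]]) -> tuple:
    if labels is None:
        seen: List[str] = []
        for lab in y:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)
    return tuple(labels)


def _make_pipeline(method: str, n_classes: int) -> Pipeline:
    priors = np.full(n_classes, 1.0 / n_classes)
    if method == "lda":
        clf = LinearDiscriminantAnalysis(solver="svd", priors=priors)
    elif method == "qda":
        # small proportional ridge keeps per-class covariances invertible
        clf = QuadraticDiscriminantAnalysis(priors=priors, reg_param=1e-6)
    else:
        raise ValueError("method must be 'lda' or 'qda'")
    return Pipeline([
        ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
        ("scale", StandardScaler()),
        ("clf", clf),
    ])


def _coerce(features: pd.DataFrame | np.ndarray, y: Sequence[str],
            labels: Optional[Sequence[str]]):
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    order = _label_order(y, labels)
    codes = np.array([order.index(lab) for lab in y])
    return X, codes, order, names


def _fit(features, y, labels, method: str) -> DiscriminantModel:
    X, codes, order, names = _coerce(features, y, labels)
    if len(order) < 2:
        raise ValueError("need at least two classes")
    if np.any(np.isnan(X).all(axis=0)):
        log.info("one or more features are entirely missing; imputed as 0 "
                 "after centering")
    pipe = _make_pipeline(method, len(order))
    pipe.fit(X, codes)
    return DiscriminantModel(pipeline=pipe, labels=order,
                             feature_names=names, method=method)


def fit_lda(features, y, labels: Optional[Sequence[str]] = None) -> DiscriminantModel:
    """Fit linear discriminant analysis (pooled covariance, uniform priors)."""
    return _fit(features, y, labels, "lda")


def fit_qda(features, y, labels: Optional[Sequence[str]] = None) -> DiscriminantModel:
    """Fit quadratic discriminant analysis (per-class covariances)."""
    return _fit(features, y, labels, "qda")


def predict(model: DiscriminantModel, features) -> np.ndarray:
    """Assign each row to a model label (argmax discriminant score; ties go
    to the earliest label in the declared order)."""
    if isinstance(features, pd.DataFrame):
        X = features[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    codes = model.pipeline.predict(X)
    return np.array([model.labels[c] for c in codes])


def loocv_accuracy(features, y, method: str = "lda",
                   labels: Optional[Sequence[str]] = None) -> AccuracyReport:
    """Leave-one-out cross-validated assignment accuracy.

    Refits the discriminant (including imputation and standardization) with
    each row excluded in turn, classifies the held-out row, and tallies the
    confusion matrix.
    """
    X, codes, order, names = _coerce(features, y, labels)
    n = len(codes)
    for c in range(len(order)):
        if np.sum(codes == c) < 2:
            raise ValueError("each class needs at least 2 rows for LOOCV")
    assigned = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        pipe = _make_pipeline(method, len(order))
        pipe.fit(X[train], codes[train])
        assigned[i] = pipe.predict(X[i:i + 1])[0]
    k = len(order)
    conf = np.zeros((k, k), dtype=int)
    for t, a in zip(codes, assigned):
        conf[t, a] += 1
    conf_df = pd.DataFrame(conf, index=list(order), columns=list(order))
    per_class = {order[c]: conf[c, c] / conf[c].sum() for c in range(k)}
    overall = float(np.mean(assigned == codes))
    return AccuracyReport(confusion=conf_df, per_class=per_class,
                          overall=overall, feature_names=names, method=method)
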