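"""Probability-emitting classifiers registered under the pipeline's names.

The headline model is ridge-stabilized logistic regression (penalty weak
enough to be negligible, it only conditions the optimization). The other
four names are filled by equivalent scikit-learn learners:

- ``classification_via_regression`` — one regression tree per class fitted
  to the class indicator, probabilities by normalizing the clipped outputs
- ``random_forest`` — the standard ensemble
- ``lmt`` — gradient boosting with log-loss, i.e. an additive logistic /
  tree hybrid standing in for a logistic model tree
- ``random_subspace`` — bagging of decision trees over random feature
  subspaces (half of the features, no bootstrap)
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

CLASSIFIER_NAMES = (
    "logistic",
    "classification_via_regression",
    "random_forest",
    "lmt",
    "random_subspace",
)

POSITIVE_CLASS = "up"


class ClassificationViaRegression(BaseEstimator, ClassifierMixin):
    """Classification by per-class regression on the 0/1 class indicator."""

    def __init__(self, random_state: int = 0, min_samples_leaf: int = 5):
        self.random_state = random_state
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.models_ = []
        for cls in self.classes_:
            model = DecisionTreeRegressor(
                random_state=self.random_state,
                min_samples_leaf=self.min_samples_leaf,
            )
            model.fit(X, (y == cls).astype(float))
            self.models_.append(model)
        return self

    def predict_proba(self, X):
        raw = np.column_stack([m.predict(X) for m in self.models_])
        raw = np.clip(raw, 0.0, None)
        totals = raw.sum(axis=1, keepdims=True)
        uniform = np.full_like(raw, 1.0 / raw.shape[1])
        return np.where(totals > 0, raw / np.where(totals == 0, 1.0, totals), uniform)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_classifier(name: str, seed: int = 0):
    """Instantiate an unfitted classifier by registry name."""
    if name == "logistic":
        return LogisticRegression(C=1e8, solver="lbfgs", max_iter=2000)
    if name == "classification_via_regression":
        return ClassificationViaRegression(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "lmt":
        return GradientBoostingClassifier(random_state=seed)
    if name == "random_subspace":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=10,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {name!r}")


class FittedClassifier:
    """A fitted model exposing the probability of the positive ('up') class."""

    def __init__(self, name: str, model, feature_names: Sequence[str]):
        self.name = name
        self.model = model
        self.feature_names = list(feature_names)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def prob_up(self, X) -> np.ndarray:
        probs = self.model.predict_proba(self._matrix(X))
        classes = list(self.model.classes_)
        if POSITIVE_CLASS in classes:
            return probs[:, classes.index(POSITIVE_CLASS)]
        # binary case with other labels: lexicographically last is positive
        return probs[:, -1]

    def predict(self, X) -> np.ndarray:
        return self.model.predict(self._matrix(X))


def train_classifier(
    name: str, X: pd.DataFrame, y, seed: int = 0
) -> FittedClassifier:
    """Fit a registered classifier; raises on unknown names or missing values."""
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values; impute first")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    model = make_classifier(name, seed)
    model.fit(X.to_numpy(dtype=float), y)
    return FittedClassifier(name, model, X.columns)
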