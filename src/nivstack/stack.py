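"""Three-learner stacking classifier.

Base learners: logistic regression, a random forest, and a
categorical-aware gradient-boosted tree ensemble
(:class:`~sklearn.ensemble.HistGradientBoostingClassifier`).  Their
out-of-fold predicted probabilities — each training row scored by a base
model whose training folds excluded that row — form an (n, 3) matrix on
which a logistic-regression meta learner is fit.  The base learners are
then refit on the full training data for prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["StackSpec", "FittedStack", "fit_stack", "predict_proba", "predict"]

BASE_NAMES = ("logistic", "random_forest", "gbdt")


@dataclass
class StackSpec:
    n_folds: int = 5
    decision_threshold: float = 0.5
    logistic_params: dict = field(default_factory=lambda: {"max_iter": 2000})
    forest_params: dict = field(default_factory=lambda: {"n_estimators": 200})
    gbdt_params: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, n_rows: int | None = None) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if n_rows is not None and self.n_folds > n_rows:
            raise ValueError(f"n_folds ({self.n_folds}) exceeds training rows ({n_rows})")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie strictly in (0, 1)")

    def make_base_learners(self) -> dict:
        return {
            "logistic": LogisticRegression(**self.logistic_params),
            "random_forest": RandomForestClassifier(
                random_state=self.seed, **self.forest_params
            ),
            "gbdt": HistGradientBoostingClassifier(
                random_state=self.seed, **self.gbdt_params
            ),
        }


@dataclass
class FittedStack:
    spec: StackSpec
    base_learners: dict
    meta_learner: LogisticRegression
    oof_probabilities: np.ndarray  # (n_train, 3)
    fold_assignment: np.ndarray  # (n_train,)
    feature_names: list[str] | None = None

    def _check_schema(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_names is not None:
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            return X[self.feature_names].to_numpy(float)
        X = np.asarray(X, float)
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X


def fit_stack(X, y, spec: StackSpec | None = None) -> FittedStack:
    """Fit base learners + meta learner with stratified out-of-fold
    meta-features; deterministic under ``spec.seed``."""
    spec = spec or StackSpec()
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    spec.validate(len(y))
    if np.unique(y).size != 2:
        raise ValueError("y must contain exactly two classes")

    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    oof = np.zeros((len(y), len(BASE_NAMES)))
    fold_assignment = np.full(len(y), -1, dtype=int)
    templates = spec.make_base_learners()
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if np.unique(y[tr]).size < 2:
            raise ValueError(
                "a training fold lost a class; use fewer folds or more data"
            )
        fold_assignment[te] = fold
        for j, name in enumerate(BASE_NAMES):
            model = clone(templates[name])
            model.fit(X[tr], y[tr])
            oof[te, j] = model.predict_proba(X[te])[:, 1]

    meta = LogisticRegression(max_iter=2000)
    meta.fit(oof, y)

    base = spec.make_base_learners()
    for name in BASE_NAMES:
        base[name].fit(X, y)
    return FittedStack(
        spec=spec,
        base_learners=base,
        meta_learner=meta,
        oof_probabilities=oof,
        fold_assignment=fold_assignment,
        feature_names=feature_names,
    )


def base_probabilities(stack: FittedStack, X) -> np.ndarray:
    Xv = stack._check_schema(X)
    return np.column_stack(
        [stack.base_learners[name].predict_proba(Xv)[:, 1] for name in BASE_NAMES]
    )


def predict_proba(stack: FittedStack, X) -> np.ndarray:
    """Meta-learner probability of the positive class (failure)."""
    return stack.meta_learner.predict_proba(base_probabilities(stack, X))[:, 1]


def predict(stack: FittedStack, X, threshold: float | None = None) -> np.ndarray:
    """Label 1 iff probability >= threshold (default from the spec)."""
    t = stack.spec.decision_threshold if threshold is None else threshold
    return (predict_proba(stack, X) >= t).astype(int)
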