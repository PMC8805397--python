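"""Benchmark harnesses: oversampler and classifier comparison tables.

Each harness takes an already feature-engineered train/test split,
applies one configuration per row (an oversampler feeding a fixed
logistic regression, or a classifier on a fixed oversampled set), and
reports the five-measure row computed on the held-out split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from . import stack as stack_mod
from .metrics import metrics_row
from .oversample import OVERSAMPLERS

__all__ = ["benchmark_oversamplers", "benchmark_classifiers", "CLASSIFIERS"]


def benchmark_oversamplers(
    X_train,
    y_train,
    X_test,
    y_test,
    oversamplers: list[str] | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One metrics row per oversampler, logistic regression downstream."""
    names = oversamplers or list(OVERSAMPLERS)
    if not names:
        raise ValueError("oversampler list must be non-empty")
    rows = []
    for name in names:
        sampler = OVERSAMPLERS[name]
        Xo, yo = sampler(np.asarray(X_train, float), np.asarray(y_train), seed=seed)
        clf = LogisticRegression(max_iter=2000).fit(Xo, yo)
        scores = clf.predict_proba(np.asarray(X_test, float))[:, 1]
        row = metrics_row(y_test, scores, threshold=threshold, name=name)
        row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def _make_classifiers(seed: int) -> dict:
    return {
        "logistic_regression": LogisticRegression(max_iter=2000),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "gbdt": HistGradientBoostingClassifier(random_state=seed),
        "svm": SVC(probability=True, random_state=seed),
    }


CLASSIFIERS = tuple(_make_classifiers(0)) + ("stack",)


def benchmark_classifiers(
    X_train,
    y_train,
    X_test,
    y_test,
    classifiers: list[str] | None = None,
    oversampler: str = "modified_smote",
    seed: int = 0,
    threshold: float = 0.5,
    stack_spec: stack_mod.StackSpec | None = None,
) -> pd.DataFrame:
    """One metrics row per classifier, all sharing one oversampled
    training set (default: the hard-instance cluster oversampler)."""
    available = _make_classifiers(seed)
    names = classifiers or list(available) + ["stack"]
    if not names:
        raise ValueError("classifier list must be non-empty")
    Xo, yo = OVERSAMPLERS[oversampler](
        np.asarray(X_train, float), np.asarray(y_train), seed=seed
    )
    Xt = np.asarray(X_test, float)
    rows = []
    for name in names:
        if name == "stack":
            spec = stack_spec or stack_mod.StackSpec(seed=seed)
            fitted = stack_mod.fit_stack(Xo, yo, spec)
            scores = stack_mod.predict_proba(fitted, Xt)
        else:
            clf = available[name].fit(Xo, yo)
            scores = clf.predict_proba(Xt)[:, 1]
        row = metrics_row(y_test, scores, threshold=threshold, name=name)
        row["seed"] = seed
        row["oversampler"] = oversampler
        rows.append(row)
    return pd.DataFrame(rows)
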