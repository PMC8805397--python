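"""Published reference results for the NIV-failure prediction task.

These are the evaluation tables reported by the clinical study this
package operationalizes, computed there on a private hospital cohort
(2495 patients, 80/20 split).  They are shipped as data so that
regression-style comparisons and the worked-example arithmetic (metric
deltas, explanation additivity) can be recomputed without access to the
original data.  Keys follow the ``accuracy/auc/f1/precision/recall``
metric row layout.
"""

from __future__ import annotations

__all__ = [
    "FEATURE_ABLATION",
    "OVERSAMPLER_COMPARISON",
    "CLASSIFIER_COMPARISON",
    "SEVERITY_SCORE_COMPARISON",
    "EXPLANATION_EXAMPLE",
    "COHORT",
    "delta",
]

# Logistic regression under three feature sets.
FEATURE_ABLATION = {
    "original_features": {"accuracy": 0.869, "auc": 0.905, "f1": 0.747, "precision": 0.872, "recall": 0.653},
    "manual_features": {"accuracy": 0.874, "auc": 0.907, "f1": 0.753, "precision": 0.889, "recall": 0.653},
    "all_features": {"accuracy": 0.878, "auc": 0.907, "f1": 0.770, "precision": 0.864, "recall": 0.694},
}

# Logistic regression under different oversamplers.
OVERSAMPLER_COMPARISON = {
    "random": {"accuracy": 0.844, "auc": 0.904, "f1": 0.759, "precision": 0.695, "recall": 0.837},
    "smote": {"accuracy": 0.846, "auc": 0.896, "f1": 0.749, "precision": 0.719, "recall": 0.782},
    "borderline_smote": {"accuracy": 0.836, "auc": 0.898, "f1": 0.734, "precision": 0.702, "recall": 0.769},
    "svm_smote": {"accuracy": 0.848, "auc": 0.904, "f1": 0.750, "precision": 0.726, "recall": 0.776},
    "modified_smote": {"accuracy": 0.834, "auc": 0.905, "f1": 0.758, "precision": 0.663, "recall": 0.884},
}

# All features + the modified oversampler, across classifiers.
CLASSIFIER_COMPARISON = {
    "random_forest": {"accuracy": 0.862, "auc": 0.896, "f1": 0.729, "precision": 0.861, "recall": 0.633},
    "logistic_regression": {"accuracy": 0.834, "auc": 0.905, "f1": 0.758, "precision": 0.663, "recall": 0.884},
    "catboost": {"accuracy": 0.866, "auc": 0.901, "f1": 0.755, "precision": 0.817, "recall": 0.701},
    "svm": {"accuracy": 0.832, "auc": 0.845, "f1": 0.754, "precision": 0.662, "recall": 0.878},
    "gbdt": {"accuracy": 0.862, "auc": 0.892, "f1": 0.745, "precision": 0.815, "recall": 0.687},
    "xgboost": {"accuracy": 0.858, "auc": 0.888, "f1": 0.732, "precision": 0.822, "recall": 0.66},
    "lightgbm": {"accuracy": 0.872, "auc": 0.893, "f1": 0.763, "precision": 0.837, "recall": 0.701},
    "stack": {"accuracy": 0.882, "auc": 0.915, "f1": 0.794, "precision": 0.814, "recall": 0.776},
}

# Conventional severity score vs. the stack.
SEVERITY_SCORE_COMPARISON = {
    "apache": {"accuracy": 0.713, "auc": 0.667, "f1": 0.235, "precision": 0.55, "recall": 0.15},
    "stack": {"accuracy": 0.882, "auc": 0.915, "f1": 0.794, "precision": 0.814, "recall": 0.776},
}

# Worked per-patient explanation example: average prediction over the
# test set and the explained (margin-scale) prediction for one failed-
# therapy patient with 89 features.
EXPLANATION_EXAMPLE = {
    "base_value": 0.545,
    "prediction": 1.594,
    "n_features": 89,
}

COHORT = {"n_patients": 2495, "n_failures": 740, "train_size": 1996, "test_size": 499}


def delta(metric: str, minuend: dict, subtrahend: dict, percent: bool = False) -> float:
    """Difference ``minuend[metric] - subtrahend[metric]``, optionally
    in percentage points."""
    d = minuend[metric] - subtrahend[metric]
    return 100.0 * d if percent else d
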