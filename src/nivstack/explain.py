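"""Additive per-feature attributions and global importance rankings.

Two explainers, both exactly additive (base value + sum of attributions
equals the explained prediction to floating-point error):

* a closed-form linear explainer for logistic regression, working on
  the margin (log-odds) scale: ``phi_j = beta_j * (x_j - mean(ref_j))``;
* a seeded permutation explainer for arbitrary models (forests, boosted
  trees, the full stack).  For each sampled feature permutation it walks
  from the reference distribution to the explained instance one feature
  at a time; the per-permutation contributions telescope to
  ``f(x) - E_ref[f]``, so additivity is exact regardless of how many
  permutations are averaged.

Output space is a per-model setting: margin (log-odds) where the model
exposes one, probability otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .stack import FittedStack, predict_proba as stack_predict_proba

__all__ = [
    "Explanation",
    "GlobalImportance",
    "explain_instance",
    "explain_global",
    "model_function",
]


@dataclass
class Explanation:
    instance_id: str
    base_value: float
    attributions: dict[str, float]
    prediction: float

    @property
    def attribution_sum(self) -> float:
        return float(sum(self.attributions.values()))

    def additivity_gap(self) -> float:
        return abs(self.base_value + self.attribution_sum - self.prediction)

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "base_value": self.base_value,
            "prediction": self.prediction,
            "attributions": self.attributions,
        }


@dataclass
class GlobalImportance:
    """Per-feature mean |attribution|, sorted descending."""

    importance: dict[str, float]

    @property
    def ranking(self) -> list[str]:
        return list(self.importance)


def _as_array(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def model_function(model, output: str = "auto"):
    """Return ``f(X) -> scores`` on the requested output space.

    ``auto`` picks margin (log-odds) when the model has a
    ``decision_function``, else positive-class probability.
    """
    if isinstance(model, FittedStack):
        return lambda X: stack_predict_proba(model, X)
    if output == "margin" or (output == "auto" and hasattr(model, "decision_function")):
        if hasattr(model, "decision_function"):
            return lambda X: np.asarray(model.decision_function(X), float)
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    return lambda X: np.asarray(model.predict(X), float)


def _linear_explanation(model, x, names, reference, fn_unused=None,
                        instance_id: str = "") -> Explanation:
    beta = np.asarray(model.coef_, float).ravel()
    mu = reference.mean(axis=0)
    phi = beta * (x - mu)
    base = float(mu @ beta + float(np.asarray(model.intercept_).ravel()[0]))
    pred = float(x @ beta + float(np.asarray(model.intercept_).ravel()[0]))
    return Explanation(
        instance_id=instance_id,
        base_value=base,
        attributions={n: float(v) for n, v in zip(names, phi)},
        prediction=pred,
    )


def _permutation_explanation(
    fn, x, names, reference, n_permutations: int, seed: int, instance_id: str = ""
) -> Explanation:
    rng = np.random.default_rng(seed)
    d = len(x)
    nref = len(reference)
    base = float(fn(reference).mean())
    pred = float(fn(x[None, :])[0])
    phi = np.zeros(d)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        # forward pass: reference -> x, then antithetic reverse pass.
        # All d intermediate hybrid matrices of a pass are stacked into a
        # single model call.
        for ordering in (order, order[::-1]):
            stacked = np.empty((d, nref, d))
            current = reference.copy()
            for k, j in enumerate(ordering):
                current[:, j] = x[j]
                stacked[k] = current
            vals = fn(stacked.reshape(d * nref, d)).reshape(d, nref).mean(axis=1)
            prev = base
            for k, j in enumerate(ordering):
                phi[j] += 0.5 * (vals[k] - prev) / n_permutations
                prev = vals[k]
    return Explanation(
        instance_id=instance_id,
        base_value=base,
        attributions={n: float(v) for n, v in zip(names, phi)},
        prediction=pred,
    )


def explain_instance(
    model,
    x,
    reference,
    feature_names=None,
    output: str = "auto",
    n_permutations: int = 10,
    seed: int = 0,
    instance_id: str = "",
    max_reference: int = 100,
) -> Explanation:
    """Additive explanation of one prediction against a reference set.

    Logistic-regression models get the exact closed-form linear
    explanation (margin scale); everything else goes through the seeded
    permutation explainer.  The reference set is subsampled to
    ``max_reference`` rows for tractability.
    """
    ref, names = _as_array(reference, feature_names)
    xv, _ = _as_array(x, names)
    xv = xv[0]
    if len(ref) == 0:
        raise ValueError("reference set must be non-empty")
    if xv.shape[0] != ref.shape[1]:
        raise ValueError(
            f"instance has {xv.shape[0]} features but reference has {ref.shape[1]}"
        )
    if len(ref) > max_reference:
        idx = np.random.default_rng(seed).choice(len(ref), max_reference, replace=False)
        ref = ref[idx]
    if isinstance(model, LogisticRegression) and output in ("auto", "margin"):
        return _linear_explanation(model, xv, names, ref, instance_id=instance_id)
    fn = model_function(model, output)
    return _permutation_explanation(
        fn, xv, names, ref, n_permutations, seed, instance_id=instance_id
    )


def explain_global(
    model,
    X,
    feature_names=None,
    output: str = "auto",
    n_permutations: int = 5,
    seed: int = 0,
    max_instances: int = 50,
    reference=None,
) -> GlobalImportance:
    """Mean |attribution| per feature over (a subsample of) ``X``."""
    Xv, names = _as_array(X, feature_names)
    if len(Xv) == 0:
        raise ValueError("X must be non-empty")
    ref = Xv if reference is None else _as_array(reference, names)[0]
    rng = np.random.default_rng(seed)
    rows = Xv
    if len(Xv) > max_instances:
        rows = Xv[rng.choice(len(Xv), max_instances, replace=False)]
    totals = np.zeros(len(names))
    for i, row in enumerate(rows):
        exp = explain_instance(
            model,
            row,
            ref,
            feature_names=names,
            output=output,
            n_permutations=n_permutations,
            seed=seed + i,
        )
        totals += np.abs([exp.attributions[n] for n in names])
    mean_abs = totals / len(rows)
    order = np.argsort(-mean_abs)
    return GlobalImportance(
        importance={names[j]: float(mean_abs[j]) for j in order}
    )
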