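"""Train-fitted data cleaning: outlier masking, median imputation,
z-score scaling, one-hot encoding with rare-category collapse, and the
train/test split.

All statistics (outlier bounds, medians, means, SDs, category maps) are
learned on the training split only and replayed verbatim on any other
split, so nothing leaks from held-out rows.  Standard deviations are
population (divide-by-n) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessSpec",
    "FittedPreprocessor",
    "detect_outliers",
    "impute_median",
    "zscore",
    "onehot",
    "fit_onehot",
    "split_train_test",
]

OTHERS = "Others"


@dataclass
class PreprocessSpec:
    outlier_sigma: float = 3.0
    rare_category_threshold: int = 20
    split_fraction: float = 0.8
    stratify: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.outlier_sigma <= 0:
            raise ValueError(f"outlier_sigma must be positive, got {self.outlier_sigma!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError(
                f"split_fraction must lie strictly in (0, 1), got {self.split_fraction!r}"
            )
        if self.rare_category_threshold < 0:
            raise ValueError("rare_category_threshold must be non-negative")


def detect_outliers(column, sigma_mult: float) -> np.ndarray:
    """Boolean mask of entries strictly farther than ``sigma_mult``
    population SDs from the mean of the finite entries."""
    x = np.asarray(column, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("column needs at least 2 finite values for outlier detection")
    mu = x[finite].mean()
    sd = x[finite].std()  # population SD; sd == 0 -> nothing can exceed the bound
    mask = np.zeros(x.shape, dtype=bool)
    mask[finite] = np.abs(x[finite] - mu) > sigma_mult * sd
    if sd == 0:
        mask[:] = False
    return mask


def impute_median(column, median: float) -> np.ndarray:
    """Replace non-finite entries with ``median`` (a training-split
    statistic); observed entries pass through unchanged."""
    if not np.isfinite(median):
        raise ValueError("imputation median is not finite (feature all-missing in training?)")
    x = np.asarray(column, dtype=float).copy()
    x[~np.isfinite(x)] = median
    return x


def zscore(column, mean: float, sd: float) -> np.ndarray:
    """(x - mean) / sd elementwise; ``sd`` must be positive."""
    if sd <= 0:
        raise ValueError(f"zscore requires a positive SD, got {sd!r}")
    return (np.asarray(column, dtype=float) - mean) / sd


def fit_onehot(column: pd.Series, threshold: int) -> list[str]:
    """Category list for a categorical feature: categories whose training
    count reaches ``threshold`` keep their own column; everything else
    (and any unseen test value) is routed to the catch-all ``Others``."""
    counts = column.astype(str).value_counts()
    kept = sorted(c for c in counts.index if counts[c] >= threshold and c != OTHERS)
    return kept + [OTHERS]


def onehot(
    column: pd.Series,
    category_columns: list[str] | None = None,
    threshold: int | None = None,
) -> pd.DataFrame:
    """Expand a categorical column into a 0/1 block.

    Pass a fitted ``category_columns`` list to replay a training-time
    encoding, or a ``threshold`` to fit on the column itself.  Values
    without their own column fall into ``Others``, so block row sums are
    always exactly 1.
    """
    if category_columns is None:
        if threshold is None:
            raise ValueError("provide either category_columns or threshold")
        category_columns = fit_onehot(column, threshold)
    values = column.astype(str)
    own = set(category_columns)
    routed = values.where(values.isin(own), OTHERS)
    block = pd.DataFrame(index=column.index)
    for cat in category_columns:
        block[f"{column.name}={cat}"] = (routed == cat).astype(int)
    return block


def split_train_test(
    table: pd.DataFrame, fraction: float, seed: int, stratify: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint random partition with training size = round(fraction * n)."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction!r}")
    rng = np.random.default_rng(seed)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    if stratify and "niv_failure" in table.columns:
        groups = [
            grp.index.to_numpy() for _, grp in table.groupby("niv_failure", sort=True)
        ]
        for idx in groups:
            rng.shuffle(idx)
        # largest-remainder allocation so the training sizes sum to n_train
        quotas = [fraction * len(idx) for idx in groups]
        takes = [int(np.floor(q)) for q in quotas]
        remainder = n_train - sum(takes)
        order = np.argsort([takes[i] - quotas[i] for i in range(len(groups))])
        for i in order[:max(remainder, 0)]:
            takes[i] += 1
        train_idx = np.concatenate([idx[:t] for idx, t in zip(groups, takes)])
        test_idx = np.concatenate([idx[t:] for idx, t in zip(groups, takes)])
        return table.loc[train_idx].copy(), table.loc[test_idx].copy()
    perm = table.index.to_numpy().copy()
    rng.shuffle(perm)
    train = table.loc[perm[:n_train]].copy()
    test = table.loc[perm[n_train:]].copy()
    return train, test


@dataclass
class FittedPreprocessor:
    """Per-feature training statistics plus the transform that replays
    them: mask outliers -> impute medians -> z-score -> one-hot."""

    spec: PreprocessSpec
    numeric_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    category_maps: dict[str, list[str]] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    passthrough: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        train: pd.DataFrame,
        numeric_columns: list[str],
        categorical_columns: list[str] | None = None,
        passthrough: list[str] | None = None,
        spec: PreprocessSpec | None = None,
    ) -> "FittedPreprocessor":
        spec = spec or PreprocessSpec()
        spec.validate()
        categorical_columns = categorical_columns or []
        self = cls(spec=spec, passthrough=list(passthrough or []))

        for col in numeric_columns:
            x = train[col].to_numpy(dtype=float)
            finite = np.isfinite(x)
            if finite.sum() < 2:
                raise ValueError(f"feature {col!r} has < 2 observed training values")
            mu0 = x[finite].mean()
            sd0 = x[finite].std()
            # The sigma rule targets continuous measurements; binary
            # flags would have their minority value masked wholesale.
            apply_rule = np.unique(x[finite]).size > 2
            mask = detect_outliers(x, spec.outlier_sigma) if apply_rule else np.zeros(
                x.shape, dtype=bool
            )
            clean = x.copy()
            clean[mask] = np.nan
            observed = clean[np.isfinite(clean)]
            if observed.size == 0:
                raise ValueError(f"feature {col!r} entirely masked/missing in training")
            median = float(np.median(observed))
            filled = impute_median(clean, median)
            mean = float(filled.mean())
            sd = float(filled.std())
            if sd == 0.0:
                logger.warning("dropping zero-variance feature %r", col)
                self.dropped.append(col)
                continue
            self.numeric_stats[col] = {
                "apply_outlier_rule": bool(apply_rule),
                "pre_mean": float(mu0),
                "pre_sd": float(sd0),
                "lower": float(mu0 - spec.outlier_sigma * sd0),
                "upper": float(mu0 + spec.outlier_sigma * sd0),
                "median": median,
                "mean": mean,
                "sd": sd,
            }

        for col in categorical_columns:
            self.category_maps[col] = fit_onehot(
                train[col], spec.rare_category_threshold
            )
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        parts = []
        if self.passthrough:
            parts.append(table[self.passthrough].reset_index(drop=True))
        num = {}
        for col, st in self.numeric_stats.items():
            x = table[col].to_numpy(dtype=float)
            finite = np.isfinite(x)
            cleaned = x.copy()
            flag = finite & (np.abs(x - st["pre_mean"]) > self.spec.outlier_sigma * st["pre_sd"])
            if st["pre_sd"] == 0 or not st.get("apply_outlier_rule", True):
                flag[:] = False
            cleaned[flag] = np.nan
            filled = impute_median(cleaned, st["median"])
            num[col] = zscore(filled, st["mean"], st["sd"])
        if num:
            parts.append(pd.DataFrame(num))
        for col, cats in self.category_maps.items():
            block = onehot(table[col], cats).reset_index(drop=True)
            parts.append(block)
        out = pd.concat(parts, axis=1)
        out.index = table.index
        return out

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.__dict__,
                "numeric_stats": self.numeric_stats,
                "category_maps": self.category_maps,
                "dropped": self.dropped,
                "passthrough": self.passthrough,
            },
            indent=2,
            # key order is semantic: transform emits columns in fit order
            sort_keys=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedPreprocessor":
        d = json.loads(text)
        return cls(
            spec=PreprocessSpec(**d["spec"]),
            numeric_stats=d["numeric_stats"],
            category_maps=d["category_maps"],
            dropped=d["dropped"],
            passthrough=d["passthrough"],
        )
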