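"""Feature generation and filtering.

Three feature families on top of the raw (already standardized) columns:

* ``manual`` — per-pair mean ``(H0+H1)/2`` and difference ``H1-H0``;
* ``expert``/``cross`` — clinician formulas (oxygenation index over RR,
  age x RR, RR x HR, RR x HR x FiO2, at both time points) and arbitrary
  pairwise products;
* ``deep`` — latent codes from the LSTM autoencoder (see
  :mod:`nivstack.lstm_autoencoder`).

Selection drops low-variance columns first, then columns whose absolute
Pearson correlation with the outcome falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "PairedFeatureMap",
    "temporal_mean_diff",
    "expert_features",
    "feature_crosses",
    "select_features",
    "pearson",
    "EXPERT_RECIPES",
]

TAGS = ("raw", "manual", "expert", "cross", "deep")


@dataclass
class FeatureMatrix:
    """Numeric matrix with named columns, each carrying exactly one
    provenance tag from ``{raw, manual, expert, cross, deep}``."""

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.data.columns:
            self.provenance.setdefault(col, "raw")
        for col, tag in self.provenance.items():
            if tag not in TAGS:
                raise ValueError(f"unknown provenance tag {tag!r} for column {col!r}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def add(self, name: str, values, tag: str) -> None:
        if tag not in TAGS:
            raise ValueError(f"unknown provenance tag {tag!r}")
        self.data[name] = values
        self.provenance[name] = tag

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.data.copy(), dict(self.provenance))

    def with_tag(self, *tags: str) -> list[str]:
        return [c for c in self.data.columns if self.provenance[c] in tags]

    def to_csv(self, path, sidecar=None) -> None:
        self.data.to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)


@dataclass
class PairedFeatureMap:
    """Triples (H0 column, H1 column, base name) describing the paired
    time-point layout of a cohort's physiological block."""

    pairs: list[tuple[str, str, str]]

    def validate(self, data: pd.DataFrame) -> None:
        seen = set()
        for h0, h1, base in self.pairs:
            for col in (h0, h1):
                if col not in data.columns:
                    raise KeyError(f"paired column {col!r} not in matrix")
                if not pd.api.types.is_numeric_dtype(data[col]):
                    raise TypeError(f"paired column {col!r} is not numeric")
            if base in seen:
                raise ValueError(f"duplicate base name {base!r}")
            seen.add(base)


def temporal_mean_diff(matrix: FeatureMatrix, pairs: PairedFeatureMap) -> FeatureMatrix:
    """Add ``<base>_mean = (H0+H1)/2`` and ``<base>_diff = H1-H0`` for
    every pair; original columns are retained."""
    pairs.validate(matrix.data)
    out = matrix.copy()
    for h0, h1, base in pairs.pairs:
        out.add(f"{base}_mean", (matrix.data[h0] + matrix.data[h1]) / 2.0, "manual")
        out.add(f"{base}_diff", matrix.data[h1] - matrix.data[h0], "manual")
    return out


# Clinician formulas: (new column, list of factor columns, kind).
# kind "ratio" divides the first factor by the second; "product"
# multiplies all factors.
EXPERT_RECIPES: list[tuple[str, list[str], str]] = [
    ("oxy_per_rr_H0", ["H0_pf_ratio", "H0_rr"], "ratio"),
    ("oxy_per_rr_H1", ["H1_pf_ratio", "H1_rr"], "ratio"),
    ("age_x_rr_H0", ["age", "H0_rr"], "product"),
    ("age_x_rr_H1", ["age", "H1_rr"], "product"),
    ("rr_x_hr_H0", ["H0_rr", "H0_hr"], "product"),
    ("rr_x_hr_H1", ["H1_rr", "H1_hr"], "product"),
    ("rr_x_hr_x_fio2_H0", ["H0_rr", "H0_hr", "H0_fio2"], "product"),
    ("rr_x_hr_x_fio2_H1", ["H1_rr", "H1_hr", "H1_fio2"], "product"),
]


def expert_features(
    matrix: FeatureMatrix, recipes: list[tuple[str, list[str], str]] | None = None
) -> FeatureMatrix:
    """Add the clinician-formula columns.

    A zero denominator in a ratio yields a missing value for that row
    (to be median-imputed downstream) and is logged.
    """
    recipes = EXPERT_RECIPES if recipes is None else recipes
    out = matrix.copy()
    for name, factors, kind in recipes:
        for col in factors:
            if col not in matrix.data.columns:
                raise KeyError(f"expert feature {name!r} needs missing column {col!r}")
        if kind == "ratio":
            num = matrix.data[factors[0]].to_numpy(float)
            den = matrix.data[factors[1]].to_numpy(float)
            zero = den == 0
            if zero.any():
                logger.warning(
                    "%d zero denominators in %r; set missing", int(zero.sum()), name
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(zero, np.nan, num / np.where(zero, np.nan, den))
        elif kind == "product":
            vals = np.ones(len(matrix.data))
            for col in factors:
                vals = vals * matrix.data[col].to_numpy(float)
        else:
            raise ValueError(f"unknown recipe kind {kind!r}")
        out.add(name, vals, "expert")
    return out


def feature_crosses(
    matrix: FeatureMatrix, pair_list: list[tuple[str, str]]
) -> FeatureMatrix:
    """Add one product column ``<a>_x_<b>`` per listed pair."""
    out = matrix.copy()
    for a, b in pair_list:
        for col in (a, b):
            if col not in matrix.data.columns:
                raise KeyError(f"cross refers to unknown column {col!r}")
        out.add(f"{a}_x_{b}", matrix.data[a] * matrix.data[b], "cross")
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation (population moments); 0 if either side is
    constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


@dataclass
class SelectionReport:
    retained: list[str]
    dropped_variance: list[str]
    dropped_pearson: list[str]
    correlations: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def select_features(
    matrix: FeatureMatrix,
    labels,
    variance_min: float = 1e-8,
    pearson_min: float = 0.01,
) -> tuple[FeatureMatrix, SelectionReport]:
    """Variance filter then |Pearson r(feature, label)| filter."""
    y = np.asarray(labels, float)
    if len(y) != len(matrix.data):
        raise ValueError("labels length does not match matrix")
    dropped_var, dropped_r, retained, corr = [], [], [], {}
    for col in matrix.data.columns:
        x = matrix.data[col].to_numpy(float)
        if x.var() < variance_min:
            dropped_var.append(col)
            continue
        r = pearson(x, y)
        corr[col] = r
        if abs(r) < pearson_min:
            dropped_r.append(col)
        else:
            retained.append(col)
    if not retained:
        raise ValueError(
            "all features dropped by selection; lower variance_min/pearson_min"
        )
    report = SelectionReport(retained, dropped_var, dropped_r, corr)
    out = FeatureMatrix(
        matrix.data[retained].copy(),
        {c: matrix.provenance[c] for c in retained},
    )
    return out, report
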