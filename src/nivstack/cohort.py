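"""Seeded synthetic ICU cohort generator.

Produces tabular cohorts with the structure the downstream pipeline
assumes: a static block (age, sex, diagnosis, comorbidity flags), paired
physiological measurements before ventilation (``H0_*``) and after one
hour (``H1_*``), H1-only ventilator settings, and a binary outcome column
``niv_failure``.  Class-conditional mean shifts at H1 give classifiers a
learnable signal; missingness, outliers and far-isolated minority points
can be injected to exercise the cleaning and oversampling stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "PHYSIOLOGIC",
    "H1_ONLY",
    "generate_cohort",
    "plant_isolated_minority",
    "paired_columns",
    "numeric_feature_columns",
    "write_cohort",
    "read_cohort",
]

OUTCOME = "niv_failure"

# (mean_H0, sd_H0, mean_H1, sd_H1, lower bound, upper bound) per paired
# physiological variable.  Values are clinically plausible ICU defaults.
PHYSIOLOGIC: dict[str, tuple[float, float, float, float, float, float]] = {
    "gcs": (14.6, 1.2, 14.6, 1.2, 3.0, 15.0),
    "sbp": (137.0, 26.0, 127.0, 23.0, 50.0, 260.0),
    "dbp": (81.0, 16.0, 74.0, 14.0, 20.0, 160.0),
    "hr": (134.0, 23.0, 104.0, 23.0, 30.0, 220.0),
    "rr": (31.0, 7.0, 27.0, 7.0, 5.0, 70.0),
    "ph": (7.36, 0.11, 7.39, 0.09, 6.8, 7.8),
    "fio2": (0.42, 0.15, 0.50, 0.16, 0.21, 1.0),
    "paco2": (57.0, 26.0, 54.0, 22.0, 15.0, 180.0),
    "pao2": (72.0, 39.0, 95.0, 40.0, 20.0, 400.0),
}

# H1-only ventilator variables: (mean, sd, lower, upper).
H1_ONLY: dict[str, tuple[float, float, float, float]] = {
    "tidal_volume": (413.0, 160.0, 50.0, 1200.0),
    "minute_ventilation": (11.2, 6.6, 1.0, 40.0),
    "insp_pressure": (15.0, 4.0, 4.0, 40.0),
    "epap": (6.0, 2.0, 2.0, 20.0),
}

# Diagnosis categories with approximate cohort proportions (13 named
# categories plus an explicit catch-all).
DEFAULT_DIAGNOSES: dict[str, float] = {
    "AECOPD": 1122,
    "Pneumonia": 652,
    "ARDS": 197,
    "Sleep_apnoea": 65,
    "Asthma": 70,
    "Heart_failure": 50,
    "Bronchiectasis": 46,
    "Sepsis": 44,
    "Pulmonary_embolism": 39,
    "TB_sequelae": 35,
    "Chest_wall_deformity": 22,
    "Obesity_hypoventilation": 6,
    "Chronic_thoracic_sequelae": 2,
    "Others": 145,
}
_total = sum(DEFAULT_DIAGNOSES.values())
DEFAULT_DIAGNOSES = {k: v / _total for k, v in DEFAULT_DIAGNOSES.items()}

COMORBIDITIES: dict[str, float] = {
    "hypertension": 889 / 2495,
    "diabetes": 493 / 2495,
    "chronic_liver_disease": 53 / 2495,
    "chronic_kidney_disease": 104 / 2495,
    "chronic_heart_disease": 201 / 2495,
    "chronic_lung_disease": 1459 / 2495,
    "immunosuppression": 100 / 2495,
    "solid_tumour": 238 / 2495,
}

# Default class-conditional standardized shifts applied at H1 (failure
# class relative to success class): failures trend toward lower GCS/pH/
# PaO2 and higher HR/RR/FiO2 after one hour of ventilation.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "gcs": -0.8,
    "ph": -0.6,
    "pao2": -0.7,
    "paco2": 0.3,
    "hr": 0.6,
    "rr": 0.7,
    "fio2": 0.6,
}


@dataclass
class CohortSpec:
    """Configuration for :func:`generate_cohort`.

    ``effect_sizes`` maps base physiological feature names (keys of
    :data:`PHYSIOLOGIC`) to the standardized mean difference between the
    failure and success class realized at H1.  ``h0_h1_correlation`` is
    the within-patient correlation between the H0 and H1 draws of a
    paired variable (not pinned down by any reference, hence exposed).
    """

    n_patients: int = 2495
    failure_rate: float = 740 / 2495
    diagnosis_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSES)
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    n_isolated_minority: int = 0
    h0_h1_correlation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 2:
            raise ValueError(f"n_patients must be an integer >= 2, got {self.n_patients!r}")
        if not 0.0 < self.failure_rate < 1.0:
            raise ValueError(f"failure_rate must lie strictly in (0, 1), got {self.failure_rate!r}")
        total = sum(self.diagnosis_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"diagnosis_distribution probabilities must sum to 1, got {total!r}"
            )
        if any(p < 0 for p in self.diagnosis_distribution.values()):
            raise ValueError("diagnosis_distribution contains a negative probability")
        for name in self.effect_sizes:
            if name not in PHYSIOLOGIC:
                raise ValueError(f"effect_sizes refers to unknown feature {name!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate!r}")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError(f"outlier_rate must lie in [0, 1), got {self.outlier_rate!r}")
        if self.n_isolated_minority < 0:
            raise ValueError("n_isolated_minority must be non-negative")
        expected_minority = self.n_patients * self.failure_rate
        if self.n_isolated_minority > expected_minority:
            raise ValueError(
                "n_isolated_minority exceeds the expected minority count "
                f"({self.n_isolated_minority} > {expected_minority:.1f})"
            )
        if not -1.0 < self.h0_h1_correlation < 1.0:
            raise ValueError("h0_h1_correlation must lie in (-1, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        return cls(**json.loads(text))


def paired_columns() -> list[tuple[str, str, str]]:
    """(H0 column, H1 column, base name) triples for all paired features."""
    pairs = [(f"H0_{n}", f"H1_{n}", n) for n in PHYSIOLOGIC]
    pairs.append(("H0_pf_ratio", "H1_pf_ratio", "pf_ratio"))
    return pairs


def numeric_feature_columns(table: pd.DataFrame) -> list[str]:
    """All numeric predictor columns (excludes id, outcome, diagnosis)."""
    skip = {OUTCOME, "patient_id", "diagnosis"}
    return [
        c
        for c in table.columns
        if c not in skip and pd.api.types.is_numeric_dtype(table[c])
    ]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort according to ``spec``.

    Deterministic for a fixed spec (including seed).  The outcome is
    drawn first at ``failure_rate``; paired physiological variables are
    then drawn class-conditionally from correlated truncated Gaussians so
    the configured H1 effect sizes appear as between-class mean
    differences while overall marginal means stay near their targets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients - spec.n_isolated_minority
    p = spec.failure_rate

    y = (rng.random(n) < p).astype(int)
    # Both classes must be present for the table to be usable downstream.
    if y.sum() == 0:
        y[rng.integers(n)] = 1
    elif y.sum() == n:
        y[rng.integers(n)] = 0

    table = pd.DataFrame({"patient_id": [f"pt{i:05d}" for i in range(n)]})
    table["age"] = np.clip(rng.normal(69.0, 14.0, n), 18.0, 100.0)
    table["sex_male"] = (rng.random(n) < 1794 / 2495).astype(int)
    diagnoses = list(spec.diagnosis_distribution)
    probs = np.asarray(list(spec.diagnosis_distribution.values()), dtype=float)
    table["diagnosis"] = rng.choice(diagnoses, size=n, p=probs / probs.sum())
    for name, prev in COMORBIDITIES.items():
        table[name] = (rng.random(n) < prev).astype(int)

    rho = spec.h0_h1_correlation
    for name, (m0, s0, m1, s1, lo, hi) in PHYSIOLOGIC.items():
        z0 = rng.standard_normal(n)
        z1 = rho * z0 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        eff = spec.effect_sizes.get(name, 0.0)
        # Mean-preserving split of the class shift: difference between the
        # class-conditional H1 means equals eff * s1.
        shift = np.where(y == 1, eff * (1.0 - p), -eff * p)
        x0 = m0 + s0 * z0
        x1 = m1 + s1 * (z1 + shift)
        table[f"H0_{name}"] = np.clip(x0, lo, hi)
        table[f"H1_{name}"] = np.clip(x1, lo, hi)
    for name, (m, s, lo, hi) in H1_ONLY.items():
        table[f"H1_{name}"] = np.clip(rng.normal(m, s, n), lo, hi)

    phys_cols = [f"H{t}_{n}" for n in PHYSIOLOGIC for t in (0, 1)]
    phys_cols += [f"H1_{n}" for n in H1_ONLY]

    if spec.outlier_rate > 0:
        # Plant gross outliers at >= 5 population SDs from the column mean
        # so that any 3-sigma rule flags them.
        for col in phys_cols:
            mask = rng.random(n) < spec.outlier_rate
            if mask.any():
                v = table[col].to_numpy(float)
                mu, sd = v.mean(), v.std()
                sd = sd if sd > 0 else 1.0
                sign = np.where(rng.random(int(mask.sum())) < 0.5, -1.0, 1.0)
                mag = 5.0 + 3.0 * rng.random(int(mask.sum()))
                v[mask] = mu + sign * mag * sd
                table[col] = v

    if spec.missing_rate > 0:
        for col in phys_cols:
            mask = rng.random(n) < spec.missing_rate
            table.loc[mask, col] = np.nan

    # Derived oxygenation index; NaN in either operand propagates so the
    # ratio identity holds wherever both operands are observed.
    table["H0_pf_ratio"] = table["H0_pao2"] / table["H0_fio2"]
    table["H1_pf_ratio"] = table["H1_pao2"] / table["H1_fio2"]

    table[OUTCOME] = y

    if spec.n_isolated_minority > 0:
        table = plant_isolated_minority(
            table, spec.n_isolated_minority, separation=15.0, seed=spec.seed + 1
        )
    return table


def plant_isolated_minority(
    table: pd.DataFrame, n: int, separation: float, seed: int
) -> pd.DataFrame:
    """Append ``n`` minority rows far from every other minority row.

    Each planted row sits at the feature-wise cohort mean plus a large
    offset along one standardized axis, scaled so its nearest minority
    neighbour (Euclidean distance in per-column standardized space) is
    farther than ``separation``.  Raises if the request is infeasible.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return table.copy()
    if (table[OUTCOME] == 1).sum() < 1:
        raise ValueError("table needs at least one minority row")

    rng = np.random.default_rng(seed)
    cols = numeric_feature_columns(table)
    base = table[cols].to_numpy(float)
    mu = np.nanmean(base, axis=0)
    sd = np.nanstd(base, axis=0)
    sd[sd == 0] = 1.0

    # Offsets are spread over all continuous physiological axes with
    # random signs: per-axis displacement stays small (so re-
    # standardizing the augmented table barely changes the geometry)
    # while total Euclidean distance is ~4x the requested separation.
    # Derived ratio columns keep their identity with pao2/fio2, so they
    # are never used as offset axes and get recomputed afterwards.
    derived = {"H0_pf_ratio", "H1_pf_ratio"}
    axes = [
        j
        for j, c in enumerate(cols)
        if c not in derived and (c.startswith("H0_") or c.startswith("H1_"))
    ]
    if not axes:
        axes = list(range(len(cols)))
    per_axis = 4.0 * separation / np.sqrt(len(axes))
    rows = []
    for _ in range(n):
        signs = np.where(rng.random(len(axes)) < 0.5, -1.0, 1.0)
        point = mu.copy()
        for k, j in enumerate(axes):
            point[j] += signs[k] * per_axis * sd[j]
        rows.append(point)

    planted = pd.DataFrame(rows, columns=cols)
    if {"H0_pao2", "H0_fio2"} <= set(cols):
        planted["H0_pf_ratio"] = planted["H0_pao2"] / planted["H0_fio2"]
        planted["H1_pf_ratio"] = planted["H1_pao2"] / planted["H1_fio2"]
    planted["patient_id"] = [f"iso{i:04d}" for i in range(n)]
    planted["diagnosis"] = table["diagnosis"].iloc[0]
    planted[OUTCOME] = 1
    for c in table.columns:
        if c not in planted.columns:
            planted[c] = table[c].iloc[0]
    planted = planted[table.columns]

    out = pd.concat([table, planted], ignore_index=True)

    # Verify the separation contract by brute force.
    minority = out[out[OUTCOME] == 1]
    z = (minority[cols].to_numpy(float) - mu) / sd
    z = np.nan_to_num(z)
    planted_mask = minority["patient_id"].str.startswith("iso").to_numpy()
    d = np.sqrt(((z[planted_mask, None, :] - z[None, ~planted_mask, :]) ** 2).sum(-1))
    within = np.sqrt(
        ((z[planted_mask, None, :] - z[None, planted_mask, :]) ** 2).sum(-1)
    )
    np.fill_diagonal(within, np.inf)
    nearest = np.minimum(d.min(axis=1), within.min(axis=1) if n > 1 else np.inf)
    if not (nearest > separation).all():
        raise ValueError(
            f"could not plant {n} isolated rows at separation {separation}"
        )
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if OUTCOME not in table.columns:
        raise ValueError(f"cohort file lacks outcome column {OUTCOME!r}")
    return table
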