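"""End-to-end orchestration: cohort -> preprocessing -> feature
engineering -> oversampling -> stacking -> evaluation -> explanation.

A single :class:`RunConfig` drives the whole run.  The global seed fans
out to per-stage seeds with a fixed additive rule (stage ``k`` uses
``seed + k``), so stages have independent randomness but the whole run
is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import stack as stack_mod
from .cohort import CohortSpec, generate_cohort, numeric_feature_columns
from .explain import explain_global, explain_instance
from .features import (
    EXPERT_RECIPES,
    FeatureMatrix,
    PairedFeatureMap,
    expert_features,
    feature_crosses,
    select_features,
    temporal_mean_diff,
)
from .lstm_autoencoder import AutoencoderSpec, encode, fit_autoencoder
from .metrics import metrics_row
from .oversample import OVERSAMPLERS, OversampleSpec, oversample
from .preprocess import FittedPreprocessor, PreprocessSpec, split_train_test

__all__ = ["RunConfig", "run", "build_features", "FeatureBundle"]

# Offsets of the per-stage seed fan-out (global seed + offset).
STAGE_SEEDS = {"cohort": 1, "split": 2, "autoencoder": 3, "oversample": 4, "stack": 5}

DEFAULT_CROSSES = [
    ("H1_rr", "H1_fio2"),
    ("H1_hr", "H1_fio2"),
    ("H0_rr", "H0_fio2"),
    ("H1_gcs", "H1_ph"),
]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: str | None = None  # load instead of simulate when set
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    oversample: OversampleSpec = field(default_factory=OversampleSpec)
    stack: stack_mod.StackSpec = field(default_factory=stack_mod.StackSpec)
    variance_min: float = 1e-8
    pearson_min: float = 0.01
    use_manual: bool = True
    use_expert: bool = True
    use_crosses: bool = True
    use_deep: bool = True
    oversampler: str = "modified_smote"
    explain_instances: int = 3
    out_dir: str = "nivstack_run"
    seed: int = 0

    def validate(self) -> None:
        if self.oversampler not in OVERSAMPLERS:
            raise ValueError(
                f"unknown oversampler {self.oversampler!r}; "
                f"choose from {sorted(OVERSAMPLERS)}"
            )
        if self.explain_instances < 0:
            raise ValueError("explain_instances must be >= 0")

    def fan_out_seeds(self) -> dict[str, int]:
        return {k: self.seed + off for k, off in STAGE_SEEDS.items()}

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=str)


@dataclass
class FeatureBundle:
    """Feature-engineered train/test split plus the fitted transformers."""

    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    provenance: dict[str, str]
    preprocessor: FittedPreprocessor
    selection_report: object
    autoencoder: object | None


def _clean_tables(cohort: pd.DataFrame, config: RunConfig):
    """Split, then fit the cleaning chain on the training rows only.

    Returns cleaned-but-unscaled train/test tables (outlier-masked and
    median-imputed on training statistics) plus the fitted preprocessor
    used later for final scaling bookkeeping.
    """
    seeds = config.fan_out_seeds()
    train_raw, test_raw = split_train_test(
        cohort, config.preprocess.split_fraction, seeds["split"],
        stratify=config.preprocess.stratify,
    )
    numeric = numeric_feature_columns(cohort)
    pre = FittedPreprocessor.fit(
        train_raw,
        numeric_columns=numeric,
        categorical_columns=["diagnosis"],
        spec=config.preprocess,
    )
    return train_raw, test_raw, pre


def _impute_unscaled(pre: FittedPreprocessor, table: pd.DataFrame) -> pd.DataFrame:
    """Outlier-mask + impute with training stats, without scaling."""
    from .preprocess import impute_median

    out = {}
    for col, st in pre.numeric_stats.items():
        x = table[col].to_numpy(float)
        finite = np.isfinite(x)
        flag = finite & (np.abs(x - st["pre_mean"]) > pre.spec.outlier_sigma * st["pre_sd"])
        if st["pre_sd"] == 0 or not st.get("apply_outlier_rule", True):
            flag[:] = False
        cleaned = x.copy()
        cleaned[flag] = np.nan
        out[col] = impute_median(cleaned, st["median"])
    return pd.DataFrame(out, index=table.index)


def build_features(cohort: pd.DataFrame, config: RunConfig) -> FeatureBundle:
    """Run the full feature-engineering stage.

    Engineered features are computed on cleaned raw-scale values; the
    final matrix is z-scored with training statistics (one-hot blocks
    pass through as 0/1).  Deep features are latent codes of an
    autoencoder fit on the training split only.
    """
    config.validate()
    seeds = config.fan_out_seeds()
    train_raw, test_raw, pre = _clean_tables(cohort, config)
    y_train = train_raw[cohort_mod.OUTCOME].to_numpy(int)
    y_test = test_raw[cohort_mod.OUTCOME].to_numpy(int)

    parts = {}
    for split, raw in (("train", train_raw), ("test", test_raw)):
        base = _impute_unscaled(pre, raw)
        fm = FeatureMatrix(base, {c: "raw" for c in base.columns})
        pairs = PairedFeatureMap(
            [p for p in cohort_mod.paired_columns() if p[0] in base.columns and p[1] in base.columns]
        )
        if config.use_manual:
            fm = temporal_mean_diff(fm, pairs)
        if config.use_expert:
            recipes = [
                r for r in EXPERT_RECIPES if all(c in fm.data.columns for c in r[1])
            ]
            fm = expert_features(fm, recipes)
        if config.use_crosses:
            crosses = [
                (a, b) for a, b in DEFAULT_CROSSES
                if a in fm.data.columns and b in fm.data.columns
            ]
            fm = feature_crosses(fm, crosses)
        parts[split] = (fm, pairs)

    fm_train, pairs = parts["train"]
    fm_test, _ = parts["test"]

    # Scale everything numeric with training statistics (huge sigma:
    # no second round of outlier masking on engineered columns).
    scaler = FittedPreprocessor.fit(
        fm_train.data,
        numeric_columns=list(fm_train.data.columns),
        spec=PreprocessSpec(
            outlier_sigma=1e12,
            rare_category_threshold=config.preprocess.rare_category_threshold,
            split_fraction=config.preprocess.split_fraction,
            seed=config.preprocess.seed,
        ),
    )
    Xtr = scaler.transform(fm_train.data)
    Xte = scaler.transform(fm_test.data)
    prov = {c: fm_train.provenance.get(c, "raw") for c in Xtr.columns}

    model = None
    if config.use_deep:
        spec = config.autoencoder
        spec = AutoencoderSpec(
            latent_dim=min(spec.latent_dim, len(pairs.pairs)),
            hidden_units=spec.hidden_units,
            epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            seed=seeds["autoencoder"],
        )
        seq_cols = pairs.pairs
        seq_train = np.stack(
            [Xtr[[h0 for h0, _, _ in seq_cols]].to_numpy(float),
             Xtr[[h1 for _, h1, _ in seq_cols]].to_numpy(float)], axis=1
        )
        seq_test = np.stack(
            [Xte[[h0 for h0, _, _ in seq_cols]].to_numpy(float),
             Xte[[h1 for _, h1, _ in seq_cols]].to_numpy(float)], axis=1
        )
        model = fit_autoencoder(seq_train, spec)
        model.feature_names = [b for _, _, b in seq_cols]
        for name, mat in (("train", seq_train), ("test", seq_test)):
            codes = encode(model, mat)
            target = Xtr if name == "train" else Xte
            for j in range(codes.shape[1]):
                target[f"deep_{j}"] = codes[:, j]
        for j in range(config.autoencoder.latent_dim):
            col = f"deep_{j}"
            if col in Xtr.columns:
                prov[col] = "deep"

    # One-hot the diagnosis block (kept 0/1, appended post-scaling).
    from .preprocess import onehot

    for col, cats in pre.category_maps.items():
        tr_block = onehot(train_raw[col], cats)
        te_block = onehot(test_raw[col], cats)
        tr_block.index = Xtr.index
        te_block.index = Xte.index
        for c in tr_block.columns:
            Xtr[c] = tr_block[c]
            Xte[c] = te_block[c]
            prov[c] = "raw"

    fm_all = FeatureMatrix(Xtr, dict(prov))
    selected, report = select_features(
        fm_all, y_train, config.variance_min, config.pearson_min
    )
    X_train = selected.data
    X_test = Xte[selected.columns].copy()
    return FeatureBundle(
        X_train=X_train,
        X_test=X_test,
        y_train=y_train,
        y_test=y_test,
        provenance=dict(selected.provenance),
        preprocessor=pre,
        selection_report=report,
        autoencoder=model,
    )


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts to
    ``config.out_dir``; returns the run report dictionary."""
    config.validate()
    seeds = config.fan_out_seeds()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.cohort_csv:
        cohort = _stage("cohort", lambda: cohort_mod.read_cohort(config.cohort_csv))
    else:
        spec = CohortSpec(**{**asdict(config.cohort), "seed": seeds["cohort"]})
        cohort = _stage("cohort", lambda: generate_cohort(spec))
    cohort_mod.write_cohort(cohort, out / "cohort.csv")

    bundle = _stage("features", lambda: build_features(cohort, config))

    def _oversample():
        if config.oversampler == "modified_smote":
            ospec = OversampleSpec(
                isolation_neighbors=config.oversample.isolation_neighbors,
                n_clusters=config.oversample.n_clusters,
                target_ratio=config.oversample.target_ratio,
                svm_kernel=config.oversample.svm_kernel,
                svm_C=config.oversample.svm_C,
                seed=seeds["oversample"],
            )
            Xo, yo, rep = oversample(
                bundle.X_train.to_numpy(float), bundle.y_train, ospec
            )
            return Xo, yo, rep
        sampler = OVERSAMPLERS[config.oversampler]
        Xo, yo = sampler(
            bundle.X_train.to_numpy(float), bundle.y_train, seed=seeds["oversample"]
        )
        return Xo, yo, {"method": config.oversampler}

    Xo, yo, os_report = _stage("oversample", _oversample)
    with open(out / "oversample_report.json", "w") as fh:
        json.dump(os_report, fh, indent=2, sort_keys=True)

    def _fit():
        sspec = stack_mod.StackSpec(
            n_folds=config.stack.n_folds,
            decision_threshold=config.stack.decision_threshold,
            logistic_params=config.stack.logistic_params,
            forest_params=config.stack.forest_params,
            gbdt_params=config.stack.gbdt_params,
            seed=seeds["stack"],
        )
        Xo_df = pd.DataFrame(Xo, columns=list(bundle.X_train.columns))
        return stack_mod.fit_stack(Xo_df, yo, sspec)

    fitted = _stage("stack", _fit)
    import joblib

    joblib.dump(fitted, out / "model.joblib")
    np.savetxt(out / "fold_assignment.txt", fitted.fold_assignment, fmt="%d")

    def _evaluate():
        scores = stack_mod.predict_proba(fitted, bundle.X_test)
        return metrics_row(
            bundle.y_test, scores, threshold=config.stack.decision_threshold,
            name="stack",
        )

    metrics = _stage("evaluate", _evaluate)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)

    explanations = []
    importance = None
    if config.explain_instances > 0:
        def _explain():
            ref = bundle.X_train
            rows = bundle.X_test.iloc[: config.explain_instances]
            exps = [
                explain_instance(
                    fitted, rows.iloc[i], ref, feature_names=list(ref.columns),
                    seed=config.seed, n_permutations=5,
                    instance_id=str(rows.index[i]),
                ).to_dict()
                for i in range(len(rows))
            ]
            imp = explain_global(
                fitted, bundle.X_test, feature_names=list(bundle.X_test.columns),
                seed=config.seed, n_permutations=3, max_instances=20,
                reference=bundle.X_train,
            )
            return exps, imp

        explanations, importance = _stage("explain", _explain)
        with open(out / "explanations.json", "w") as fh:
            json.dump(explanations, fh, indent=2, sort_keys=True)
        pd.Series(importance.importance, name="mean_abs_attribution").to_csv(
            out / "global_importance.csv"
        )

    with open(out / "selection_report.json", "w") as fh:
        fh.write(bundle.selection_report.to_json())
    with open(out / "preprocessor.json", "w") as fh:
        fh.write(bundle.preprocessor.to_json())

    manifest = {
        "config": json.loads(config.to_json()),
        "seeds": seeds,
        "n_features": int(bundle.X_train.shape[1]),
        "n_train": int(len(bundle.y_train)),
        "n_test": int(len(bundle.y_test)),
        "oversample": {k: v for k, v in os_report.items() if k != "provenance"},
        "metrics": metrics,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
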