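import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nivstack.cohort import numeric_feature_columns
from nivstack.preprocess import (
    FittedPreprocessor,
    PreprocessSpec,
    detect_outliers,
    fit_onehot,
    impute_median,
    onehot,
    split_train_test,
    zscore,
)


class TestDetectOutliers:
    def test_constant_column_no_outliers(self):
        assert not detect_outliers([5.0] * 20, 3.0).any()

    def test_single_large_value_flagged(self):
        col = np.zeros(101)
        col[-1] = 10.0
        # oracle: mean = 10/101, population sd of the column
        mu, sd = col.mean(), col.std()
        assert abs(10.0 - mu) > 3 * sd  # the derivation the mask must match
        mask = detect_outliers(col, 3.0)
        assert mask[-1]
        assert mask.sum() == 1

    def test_boundary_exactly_at_threshold_not_flagged(self):
        # [-2, 2]: mean 0, population sd exactly 2, so with sigma_mult=1
        # both points sit exactly on the bound; strict inequality keeps them
        mask = detect_outliers(np.array([-2.0, 2.0]), 1.0)
        assert not mask.any()

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            detect_outliers([np.nan, np.nan], 3.0)

    def test_flagged_entries_are_strictly_beyond(self):
        r = np.random.default_rng(1)
        col = r.standard_normal(500)
        mask = detect_outliers(col, 2.0)
        mu, sd = col.mean(), col.std()
        assert (np.abs(col[mask] - mu) > 2.0 * sd).all()
        assert (np.abs(col[~mask] - mu) <= 2.0 * sd).all()


class TestImputeMedian:
    def test_basic_fill(self):
        out = impute_median([1.0, np.nan, 3.0], 2.0)
        assert out.tolist() == [1.0, 2.0, 3.0]

    def test_identity_without_missing(self):
        x = np.array([4.0, 5.0, 6.0])
        assert impute_median(x, 99.0).tolist() == x.tolist()

    def test_idempotent(self):
        x = np.array([1.0, np.nan, 3.0])
        once = impute_median(x, 2.0)
        twice = impute_median(once, 2.0)
        assert np.array_equal(once, twice)

    def test_nonfinite_median_errors(self):
        with pytest.raises(ValueError):
            impute_median([1.0, np.nan], np.nan)


class TestZscore:
    def test_worked_example(self):
        # x' = (x - mean)/sd with population sd of [2,4,6] = 1.63299...
        out = zscore([2.0, 4.0, 6.0], 4.0, np.std([2.0, 4.0, 6.0]))
        assert out == pytest.approx([-1.22474, 0.0, 1.22474], abs=1e-5)

    def test_constant_at_mean_gives_zeros(self):
        assert zscore([4.0, 4.0], 4.0, 2.0).tolist() == [0.0, 0.0]

    def test_sigma_zero_errors(self):
        with pytest.raises(ValueError):
            zscore([1.0], 0.0, 0.0)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
        st.floats(-100, 100),
        st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_property(self, xs, mean, sd):
        x = np.asarray(xs)
        back = zscore(x, mean, sd) * sd + mean
        assert np.allclose(back, x, atol=1e-6, rtol=1e-9)


class TestOnehot:
    def test_rare_category_collapsed(self):
        col = pd.Series(["A"] * 50 + ["B"] * 30 + ["C"] * 5, name="dx")
        cats = fit_onehot(col, 20)
        assert cats == ["A", "B", "Others"]
        block = onehot(col, cats)
        c_rows = block.iloc[80:]
        assert (c_rows["dx=Others"] == 1).all()

    def test_threshold_zero_keeps_every_category(self):
        col = pd.Series(["A", "B", "C"], name="dx")
        cats = fit_onehot(col, 0)
        for c in ("A", "B", "C"):
            assert c in cats

    def test_row_sums_are_one(self, small_cohort):
        block = onehot(small_cohort["diagnosis"], threshold=10)
        assert (block.sum(axis=1) == 1).all()

    def test_unseen_test_category_maps_to_others(self):
        train = pd.Series(["A"] * 30 + ["B"] * 30, name="dx")
        cats = fit_onehot(train, 20)
        test = pd.Series(["A", "Z"], name="dx")
        block = onehot(test, cats)
        assert block.loc[1, "dx=Others"] == 1
        assert block.loc[0, "dx=A"] == 1


class TestSplit:
    def test_published_cohort_arithmetic(self):
        table = pd.DataFrame({"x": range(2495)})
        train, test = split_train_test(table, 0.8, seed=0)
        assert (len(train), len(test)) == (1996, 499)

    def test_even_split(self):
        table = pd.DataFrame({"x": range(10)})
        train, test = split_train_test(table, 0.5, seed=1)
        assert (len(train), len(test)) == (5, 5)

    def test_partition_property(self):
        table = pd.DataFrame({"x": range(101)})
        train, test = split_train_test(table, 0.8, seed=3)
        assert set(train["x"]) | set(test["x"]) == set(range(101))
        assert not set(train["x"]) & set(test["x"])

    def test_deterministic(self):
        table = pd.DataFrame({"x": range(50)})
        a, _ = split_train_test(table, 0.7, seed=9)
        b, _ = split_train_test(table, 0.7, seed=9)
        assert a["x"].tolist() == b["x"].tolist()

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            split_train_test(pd.DataFrame({"x": [1]}), 0.8, seed=0)

    def test_stratified_preserves_class_fractions(self, small_cohort):
        train, test = split_train_test(small_cohort, 0.8, seed=4, stratify=True)
        assert len(train) == round(0.8 * len(small_cohort))
        p_all = small_cohort["niv_failure"].mean()
        assert train["niv_failure"].mean() == pytest.approx(p_all, abs=0.02)


class TestFittedPreprocessor:
    def _fit(self, cohort, **spec_kw):
        return FittedPreprocessor.fit(
            cohort,
            numeric_columns=numeric_feature_columns(cohort),
            categorical_columns=["diagnosis"],
            spec=PreprocessSpec(**spec_kw),
        )

    def test_training_output_standardized(self, messy_cohort):
        pre = self._fit(messy_cohort)
        out = pre.transform(messy_cohort)
        scaled = [c for c in pre.numeric_stats]
        means = out[scaled].mean()
        sds = out[scaled].std(ddof=0)
        assert means.abs().max() < 1e-9
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_no_leakage_from_test_rows(self, messy_cohort):
        train, test = split_train_test(messy_cohort, 0.8, seed=0)
        pre1 = self._fit(train)
        # mangle the test rows arbitrarily; the fit must not change
        test2 = test.copy()
        num = numeric_feature_columns(test2)
        test2[num] = test2[num] * 100 + 7
        pre2 = self._fit(train)
        assert pre1.to_json() == pre2.to_json()

    def test_test_column_imputed_with_training_median(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "niv_failure": [0, 1, 0]})
        test = pd.DataFrame({"a": [100.0, np.nan], "niv_failure": [0, 1]})
        pre = FittedPreprocessor.fit(
            train, numeric_columns=["a"], spec=PreprocessSpec(outlier_sigma=1e6)
        )
        out = pre.transform(test)
        st = pre.numeric_stats["a"]
        assert st["median"] == 2.0
        # the NaN entry must be imputed at the *train* median then scaled
        expected = (2.0 - st["mean"]) / st["sd"]
        assert out["a"].iloc[1] == pytest.approx(expected)

    def test_transform_is_reproducible_bitwise(self, messy_cohort):
        pre = self._fit(messy_cohort)
        a = pre.transform(messy_cohort)
        b = pre.transform(messy_cohort)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variance_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"a": [3.0] * 10, "b": np.arange(10.0)})
        pre = FittedPreprocessor.fit(df, numeric_columns=["a", "b"])
        assert "a" in pre.dropped
        assert "a" not in pre.numeric_stats
        assert "b" in pre.numeric_stats

    def test_json_roundtrip(self, messy_cohort):
        pre = self._fit(messy_cohort)
        back = FittedPreprocessor.from_json(pre.to_json())
        a = pre.transform(messy_cohort)
        b = back.transform(messy_cohort)
        pd.testing.assert_frame_equal(a, b)

    def test_binary_flags_not_outlier_masked(self, small_cohort):
        pre = self._fit(small_cohort)
        # rare comorbidity flags must survive (nonzero variance kept)
        assert "solid_tumour" in pre.numeric_stats
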