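import numpy as np
import pytest

from nivstack.cohort import CohortSpec, generate_cohort, numeric_feature_columns
from nivstack.oversample import (
    OVERSAMPLERS,
    HardInstanceSet,
    OversampleSpec,
    cluster_hard,
    find_hard_instances,
    oversample,
    remove_isolated,
    synthesize,
)


@pytest.fixture(scope="module")
def overlap_data():
    rng = np.random.default_rng(31)
    X = np.vstack([rng.standard_normal((180, 4)), rng.standard_normal((40, 4)) + 0.8])
    y = np.array([0] * 180 + [1] * 40)
    return X, y


class TestFindHardInstances:
    def test_separable_data_empty_hard_set(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((50, 2)), rng.standard_normal((20, 2)) + 20])
        y = np.array([0] * 50 + [1] * 20)
        hard = find_hard_instances(X, y, OversampleSpec(seed=1))
        assert hard.indices.size == 0

    def test_minority_point_inside_majority_cluster_is_hard(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [
                rng.standard_normal((100, 2)) * 0.3,  # dense majority blob
                rng.standard_normal((15, 2)) * 0.3 + 8,  # far minority blob
                [[0.0, 0.0]],  # minority point buried in the majority
            ]
        )
        y = np.array([0] * 100 + [1] * 16)
        hard = find_hard_instances(X, y, OversampleSpec(seed=2))
        assert 115 in hard.indices

    def test_hard_set_subset_of_minority(self, overlap_data):
        X, y = overlap_data
        hard = find_hard_instances(X, y, OversampleSpec(seed=3))
        assert np.all(y[hard.indices] == 1)

    def test_single_minority_point_errors(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            find_hard_instances(X, y, OversampleSpec())


class TestRemoveIsolated:
    def test_planted_isolated_point_removed(self):
        table = generate_cohort(CohortSpec(n_patients=300, seed=6, n_isolated_minority=2))
        cols = numeric_feature_columns(table)
        X = table[cols].to_numpy(float)
        X = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        y = table["niv_failure"].to_numpy()
        planted = np.where(table["patient_id"].str.startswith("iso"))[0]
        hard = HardInstanceSet(indices=planted)
        out = remove_isolated(hard, X, y, m=5)
        assert set(planted) <= set(out.isolated)

    def test_minority_twin_at_zero_distance_retained(self):
        X = np.vstack([np.zeros((2, 3)), np.ones((10, 3)) * 5])
        y = np.array([1, 1] + [0] * 10)
        hard = HardInstanceSet(indices=np.array([0]))
        out = remove_isolated(hard, X, y, m=5)
        assert out.isolated.size == 0
        assert 0 in out.retained

    def test_m_larger_than_n_nothing_isolated(self, overlap_data):
        X, y = overlap_data
        hard = HardInstanceSet(indices=np.where(y == 1)[0][:5])
        out = remove_isolated(hard, X, y, m=len(X) + 10)
        assert out.isolated.size == 0

    def test_brute_force_agreement(self, overlap_data):
        """Independent check over all hard candidates: m-NN label rule
        plus the remote-point rule (nearest minority beyond 3*sqrt(2p))."""
        X, y = overlap_data
        hard = find_hard_instances(X, y, OversampleSpec(seed=4))
        m = 5
        out = remove_isolated(hard, X, y, m)
        cut = 3.0 * np.sqrt(2.0 * X.shape[1])
        for idx in hard.indices:
            d = np.sqrt(((X - X[idx]) ** 2).sum(1))
            d[idx] = np.inf
            nearest = np.argsort(d, kind="stable")[:m]
            no_min_nearby = not (y[nearest] == 1).any()
            others = (y == 1) & (np.arange(len(y)) != idx)
            remote = d[others].min() > cut
            assert (idx in out.isolated) == (no_min_nearby or remote)


class TestClusterHard:
    def test_single_cluster_is_mean(self, rng):
        pts = rng.normal(size=(20, 3))
        labels, centroids = cluster_hard(pts, 1, seed=0)
        assert np.allclose(centroids[0], pts.mean(0))
        assert (labels == 0).all()

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((30, 2)) * 0.2
        b = rng.standard_normal((30, 2)) * 0.2 + 10
        labels, centroids = cluster_hard(np.vstack([a, b]), 2, seed=1)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_centroids_are_cluster_means(self, rng):
        pts = rng.normal(size=(50, 4))
        labels, centroids = cluster_hard(pts, 4, seed=2)
        for k in range(centroids.shape[0]):
            assert np.allclose(centroids[k], pts[labels == k].mean(0), atol=1e-9)

    def test_auto_rule(self, rng):
        pts = rng.normal(size=(25, 2))
        labels, centroids = cluster_hard(pts, "auto", seed=3)
        assert centroids.shape[0] == 5  # round(sqrt(25))


class TestSynthesize:
    def test_single_point_cluster_degenerate(self):
        pts = np.array([[2.0, 3.0]])
        batch = synthesize(pts, np.array([7]), np.array([0]), pts.copy(), 5, seed=0)
        assert np.allclose(batch.rows, [2.0, 3.0])
        assert (batch.seed_indices == 7).all()

    def test_rows_on_centroid_seed_segment(self, rng):
        pts = rng.normal(size=(30, 5))
        labels, centroids = cluster_hard(pts, 3, seed=1)
        batch = synthesize(pts, np.arange(30), labels, centroids, 100, seed=2)
        for i in range(100):
            expected = batch.centroids[i] + batch.u[i] * (
                pts[batch.seed_indices[i]] - batch.centroids[i]
            )
            assert np.abs(batch.rows[i] - expected).max() < 1e-9

    def test_zero_needed_empty(self):
        pts = np.ones((3, 2))
        batch = synthesize(pts, np.arange(3), np.zeros(3, int), np.ones((1, 2)), 0, seed=0)
        assert batch.rows.shape == (0, 2)

    def test_negative_needed_errors(self):
        with pytest.raises(ValueError):
            synthesize(np.ones((2, 2)), np.arange(2), np.zeros(2, int), np.ones((1, 2)), -1, 0)


class TestOversample:
    def test_balanced_input_noop(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 20 + [1] * 20)
        Xo, yo, report = oversample(X, y, OversampleSpec(seed=0))
        assert np.array_equal(Xo, X)
        assert np.array_equal(yo, y)
        assert report["method"] == "none"

    def test_counting_90_10(self, rng):
        X = np.vstack([rng.normal(size=(90, 3)), rng.normal(size=(10, 3)) + 0.5])
        y = np.array([0] * 90 + [1] * 10)
        Xo, yo, _ = oversample(X, y, OversampleSpec(seed=1))
        assert len(yo) == 180
        assert (yo == 1).sum() == 90
        # originals unchanged and first
        assert np.array_equal(Xo[:100], X)

    def test_deterministic(self, rng):
        X = np.vstack([rng.normal(size=(80, 3)), rng.normal(size=(20, 3)) + 0.5])
        y = np.array([0] * 80 + [1] * 20)
        a = oversample(X, y, OversampleSpec(seed=5))
        b = oversample(X, y, OversampleSpec(seed=5))
        assert np.array_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            oversample(np.ones((5, 2)), np.ones(5), OversampleSpec())

    def test_fallback_on_separable_data_still_balances(self, caplog):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.standard_normal((60, 2)), rng.standard_normal((10, 2)) + 30])
        y = np.array([0] * 60 + [1] * 10)
        Xo, yo, report = oversample(X, y, OversampleSpec(seed=2))
        assert report["method"] == "fallback_smote"
        assert (yo == 1).sum() == (yo == 0).sum()

    def test_isolated_never_seed_synthesis(self):
        table = generate_cohort(
            CohortSpec(n_patients=400, failure_rate=0.15, seed=13, n_isolated_minority=3)
        )
        cols = numeric_feature_columns(table)
        X = table[cols].to_numpy(float)
        X = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        y = table["niv_failure"].to_numpy()
        planted = set(np.where(table["patient_id"].str.startswith("iso"))[0])
        Xo, yo, report = oversample(X, y, OversampleSpec(seed=3))
        if report["method"] == "hard_instance_cluster":
            seeds = {p["seed_index"] for p in report["provenance"]}
            assert not (seeds & planted)

    def test_target_ratio_below_one(self, rng):
        X = np.vstack([rng.normal(size=(100, 3)), rng.normal(size=(10, 3)) + 0.5])
        y = np.array([0] * 100 + [1] * 10)
        Xo, yo, _ = oversample(X, y, OversampleSpec(seed=1, target_ratio=0.5))
        assert (yo == 1).sum() == 50


class TestBaselines:
    @pytest.mark.parametrize("name", ["random", "smote", "borderline_smote", "svm_smote", "modified_smote"])
    def test_each_balances_and_is_deterministic(self, name, overlap_data):
        X, y = overlap_data
        sampler = OVERSAMPLERS[name]
        Xa, ya = sampler(X, y, seed=7)
        Xb, yb = sampler(X, y, seed=7)
        assert (ya == 1).sum() == (ya == 0).sum()
        assert np.array_equal(Xa, Xb)
        assert np.array_equal(Xa[: len(y)], X)
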