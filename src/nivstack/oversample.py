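"""Hard-instance cluster oversampling and baseline oversamplers.

The main algorithm rebalances a binary dataset in four steps:

1. fit a probe SVM (RBF) on the full training partition and collect the
   minority rows it misclassifies in-sample ("hard instances");
2. drop hard instances that are *isolated* — no minority point among
   their ``m`` nearest neighbours, or no minority point within the data
   scale at all — so noise and remote points never seed synthesis;
3. k-means-cluster the retained hard instances into ``N`` clusters;
4. synthesize minority rows on the segment between a cluster centroid
   ``c`` and a member ``x``:  ``x_new = c + u * (x - c)``, ``u ~ U(0,1)``,
   sampling clusters proportionally to size, until the minority/majority
   ratio reaches the target.

If the hard set comes out empty (e.g. separable data) or fully isolated,
the sampler falls back to classic k-NN interpolation over all minority
rows, with a logged warning, so the balance contract still holds.

Baselines (random duplication, classic SMOTE, borderline SMOTE, SVM
SMOTE) expose the same ``(X, y) -> (X', y')`` signature for benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "OversampleSpec",
    "HardInstanceSet",
    "SyntheticBatch",
    "find_hard_instances",
    "remove_isolated",
    "cluster_hard",
    "synthesize",
    "oversample",
    "random_oversample",
    "smote",
    "borderline_smote",
    "svm_smote",
    "OVERSAMPLERS",
]


@dataclass
class OversampleSpec:
    isolation_neighbors: int = 5
    n_clusters: int | str = "auto"
    target_ratio: float = 1.0
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.isolation_neighbors < 1:
            raise ValueError("isolation_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.n_clusters != "auto" and (
            not isinstance(self.n_clusters, (int, np.integer)) or self.n_clusters < 1
        ):
            raise ValueError("n_clusters must be a positive integer or 'auto'")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")


@dataclass
class HardInstanceSet:
    """Minority rows misclassified by the probe SVM, with isolation
    flags filled in by :func:`remove_isolated`."""

    indices: np.ndarray  # minority row indices in X
    isolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def retained(self) -> np.ndarray:
        return np.setdiff1d(self.indices, self.isolated)


@dataclass
class SyntheticBatch:
    """Synthesized minority rows plus full per-row provenance."""

    rows: np.ndarray  # (k, p)
    cluster_ids: np.ndarray  # (k,)
    centroids: np.ndarray  # (k, p) centroid used for each row
    seed_indices: np.ndarray  # (k,) index into X of the seed instance
    u: np.ndarray  # (k,) interpolation coefficients in [0, 1]

    def provenance(self) -> list[dict]:
        return [
            {
                "cluster": int(self.cluster_ids[i]),
                "centroid": [float(v) for v in self.centroids[i]],
                "seed_index": int(self.seed_indices[i]),
                "u": float(self.u[i]),
            }
            for i in range(len(self.rows))
        ]


def _minority_label(y: np.ndarray) -> int:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return int(classes[np.argmin(counts)])


def find_hard_instances(X, y, spec: OversampleSpec) -> HardInstanceSet:
    """Minority rows whose in-sample probe-SVM prediction is wrong."""
    spec.validate()
    X = np.asarray(X, float)
    y = np.asarray(y)
    minority = _minority_label(y)
    if (y == minority).sum() < 2:
        raise ValueError("need at least 2 minority rows")
    probe = SVC(kernel=spec.svm_kernel, C=spec.svm_C, gamma="scale",
                random_state=spec.seed)
    probe.fit(X, y)
    pred = probe.predict(X)
    idx = np.where((y == minority) & (pred != minority))[0]
    return HardInstanceSet(indices=idx)


def remove_isolated(
    hard: HardInstanceSet, X, y, m: int, remote_scale: float = 3.0
) -> HardInstanceSet:
    """Flag hard instances with no minority support as isolated.

    An instance is isolated when either

    * none of its ``m`` nearest neighbours (all classes, excluding
      itself) is minority — the buried-in-majority noise case; or
    * its nearest minority neighbour is farther than
      ``remote_scale * sqrt(2p)``, the expected distance between two
      standardized points — the remote-point case, which the
      neighbour-label rule alone cannot detect because a far-away
      point's nearest neighbours are an arbitrary mix of both classes.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y)
    if hard.indices.size == 0:
        return HardInstanceSet(indices=hard.indices.copy())
    minority = _minority_label(y)
    k = min(m + 1, len(X))  # +1 because the query point is its own 0-NN
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, neigh = nn.kneighbors(X[hard.indices])
    min_rows = np.where(y == minority)[0]
    remote_cut = remote_scale * np.sqrt(2.0 * X.shape[1])
    isolated = []
    for row, idx in zip(neigh, hard.indices):
        others = [j for j in row if j != idx][:m]
        no_minority_nearby = not any(y[j] == minority for j in others)
        other_min = min_rows[min_rows != idx]
        if other_min.size:
            d_min = np.sqrt(((X[other_min] - X[idx]) ** 2).sum(axis=1)).min()
        else:
            d_min = np.inf
        if no_minority_nearby or d_min > remote_cut:
            isolated.append(idx)
    return HardInstanceSet(
        indices=hard.indices.copy(), isolated=np.asarray(isolated, dtype=int)
    )


def cluster_hard(points: np.ndarray, n_clusters, seed: int):
    """k-means partition of the retained hard instances.

    Returns (labels, centroids).  ``n_clusters='auto'`` uses
    max(1, round(sqrt(#points))); the cluster count never exceeds the
    number of points.
    """
    points = np.asarray(points, float)
    if len(points) == 0:
        raise ValueError("no points to cluster")
    if n_clusters == "auto":
        n_clusters = max(1, int(round(np.sqrt(len(points)))))
    k = min(int(n_clusters), len(points))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(points)
    return labels, km.cluster_centers_


def synthesize(
    points: np.ndarray,
    point_indices: np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
    n_needed: int,
    seed: int,
) -> SyntheticBatch:
    """Emit ``n_needed`` rows on centroid->member segments.

    Clusters are drawn proportionally to their size, the seed member
    uniformly within the cluster, and the interpolation coefficient
    ``u`` uniformly on [0, 1]:  ``row = centroid + u * (member - centroid)``.
    """
    if n_needed < 0:
        raise ValueError("n_needed must be non-negative")
    points = np.asarray(points, float)
    point_indices = np.asarray(point_indices)
    labels = np.asarray(labels)
    p = points.shape[1]
    if n_needed == 0:
        return SyntheticBatch(
            rows=np.empty((0, p)),
            cluster_ids=np.empty(0, int),
            centroids=np.empty((0, p)),
            seed_indices=np.empty(0, int),
            u=np.empty(0),
        )
    rng = np.random.default_rng(seed)
    member_pos = rng.integers(0, len(points), size=n_needed)  # uniform over
    # members == cluster choice proportional to cluster size, member
    # uniform within cluster
    cid = labels[member_pos]
    cent = centroids[cid]
    seeds = points[member_pos]
    u = rng.random(n_needed)
    rows = cent + u[:, None] * (seeds - cent)
    return SyntheticBatch(
        rows=rows,
        cluster_ids=cid,
        centroids=cent,
        seed_indices=point_indices[member_pos],
        u=u,
    )


def oversample(X, y, spec: OversampleSpec | None = None):
    """Full pipeline; returns (X', y', report).

    Original rows come first and unchanged; synthetic minority rows are
    appended until minority/majority reaches ``spec.target_ratio``.
    """
    spec = spec or OversampleSpec()
    spec.validate()
    X = np.asarray(X, float)
    y = np.asarray(y)
    minority = _minority_label(y)
    n_min = int((y == minority).sum())
    n_maj = int(len(y) - n_min)
    n_needed = int(round(spec.target_ratio * n_maj)) - n_min
    report: dict = {"minority_label": minority, "n_synthetic": max(n_needed, 0)}
    if n_needed <= 0:
        report["method"] = "none"
        return X.copy(), y.copy(), report

    hard = find_hard_instances(X, y, spec)
    hard = remove_isolated(hard, X, y, spec.isolation_neighbors)
    retained = hard.retained
    report["n_hard"] = int(hard.indices.size)
    report["n_isolated"] = int(hard.isolated.size)

    if retained.size == 0:
        logger.warning(
            "hard-instance set empty after isolation removal; "
            "falling back to classic k-NN interpolation"
        )
        Xs = _smote_rows(X, y, minority, n_needed, k=5, seed=spec.seed)
        report["method"] = "fallback_smote"
        report["provenance"] = []
    else:
        labels, centroids = cluster_hard(X[retained], spec.n_clusters, spec.seed)
        batch = synthesize(
            X[retained], retained, labels, centroids, n_needed, spec.seed
        )
        Xs = batch.rows
        report["method"] = "hard_instance_cluster"
        report["n_clusters"] = int(centroids.shape[0])
        report["provenance"] = batch.provenance()

    X_out = np.vstack([X, Xs])
    y_out = np.concatenate([y, np.full(len(Xs), minority, dtype=y.dtype)])
    return X_out, y_out, report


# ---------------------------------------------------------------------------
# baseline oversamplers (same signature, for benchmark tables)
# ---------------------------------------------------------------------------


def _needed(y, minority, target_ratio):
    n_min = int((y == minority).sum())
    n_maj = len(y) - n_min
    return int(round(target_ratio * n_maj)) - n_min


def _append(X, y, rows, minority):
    if len(rows) == 0:
        return X.copy(), y.copy()
    return (
        np.vstack([X, rows]),
        np.concatenate([y, np.full(len(rows), minority, dtype=y.dtype)]),
    )


def _smote_rows(X, y, minority, n_needed, k, seed, seed_pool=None):
    """Classic interpolation: seed minority point toward one of its k
    nearest minority neighbours."""
    rng = np.random.default_rng(seed)
    min_idx = np.where(y == minority)[0]
    pool = min_idx if seed_pool is None else np.asarray(seed_pool)
    Xmin = X[min_idx]
    k_eff = min(k, len(min_idx) - 1)
    if k_eff < 1:
        # single minority point: duplicate it
        return np.repeat(X[pool[:1]], n_needed, axis=0)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    _, neigh_all = nn.kneighbors(X[pool])
    rows = np.empty((n_needed, X.shape[1]))
    for i in range(n_needed):
        pi = rng.integers(len(pool))
        s = pool[pi]
        cand = [min_idx[j] for j in neigh_all[pi] if min_idx[j] != s][:k_eff]
        t = cand[rng.integers(len(cand))]
        u = rng.random()
        rows[i] = X[s] + u * (X[t] - X[s])
    return rows


def random_oversample(X, y, seed: int = 0, target_ratio: float = 1.0):
    X = np.asarray(X, float)
    y = np.asarray(y)
    minority = _minority_label(y)
    n_needed = _needed(y, minority, target_ratio)
    if n_needed <= 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    min_idx = np.where(y == minority)[0]
    picks = rng.choice(min_idx, size=n_needed, replace=True)
    return _append(X, y, X[picks], minority)


def smote(X, y, seed: int = 0, target_ratio: float = 1.0, k: int = 5):
    X = np.asarray(X, float)
    y = np.asarray(y)
    minority = _minority_label(y)
    n_needed = _needed(y, minority, target_ratio)
    if n_needed <= 0:
        return X.copy(), y.copy()
    return _append(X, y, _smote_rows(X, y, minority, n_needed, k, seed), minority)


def borderline_smote(X, y, seed: int = 0, target_ratio: float = 1.0, k: int = 5, m: int = 10):
    """Borderline variant: only 'danger' minority points (at least half
    of their m neighbours majority, but not all) seed interpolation."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    minority = _minority_label(y)
    n_needed = _needed(y, minority, target_ratio)
    if n_needed <= 0:
        return X.copy(), y.copy()
    min_idx = np.where(y == minority)[0]
    m_eff = min(m + 1, len(X))
    nn = NearestNeighbors(n_neighbors=m_eff).fit(X)
    _, neigh = nn.kneighbors(X[min_idx])
    danger = []
    for row, idx in zip(neigh, min_idx):
        others = [j for j in row if j != idx][: m_eff - 1]
        n_maj = sum(1 for j in others if y[j] != minority)
        if len(others) / 2.0 <= n_maj < len(others):
            danger.append(idx)
    pool = np.asarray(danger) if danger else min_idx
    return _append(
        X, y, _smote_rows(X, y, minority, n_needed, k, seed, seed_pool=pool), minority
    )


def svm_smote(X, y, seed: int = 0, target_ratio: float = 1.0, k: int = 5):
    """SVM variant: minority support vectors of an RBF SVM seed the
    interpolation."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    minority = _minority_label(y)
    n_needed = _needed(y, minority, target_ratio)
    if n_needed <= 0:
        return X.copy(), y.copy()
    svc = SVC(kernel="rbf", gamma="scale", random_state=seed).fit(X, y)
    sv = svc.support_[y[svc.support_] == minority]
    pool = sv if sv.size else np.where(y == minority)[0]
    return _append(
        X, y, _smote_rows(X, y, minority, n_needed, k, seed, seed_pool=pool), minority
    )


def modified_smote(X, y, seed: int = 0, target_ratio: float = 1.0, **kwargs):
    """Signature-compatible wrapper around :func:`oversample`."""
    spec = OversampleSpec(seed=seed, target_ratio=target_ratio, **kwargs)
    Xo, yo, _ = oversample(X, y, spec)
    return Xo, yo


OVERSAMPLERS = {
    "none": lambda X, y, seed=0, target_ratio=1.0: (np.asarray(X, float).copy(), np.asarray(y).copy()),
    "random": random_oversample,
    "smote": smote,
    "borderline_smote": borderline_smote,
    "svm_smote": svm_smote,
    "modified_smote": modified_smote,
}
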