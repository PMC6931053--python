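"""Daily-behavior clustering: normalization, elbow k selection, k-means,
activity ordering, and cluster achievement values.

Subject-days are clustered on the 5-feature behavior vector (light /
moderate / vigorous minutes, steps, step-goal flag).  Numerical features are
normalized (z-score by default); the binary flag enters the distance raw as
0/1.  The number of clusters can be chosen automatically by the elbow rule
on the within-cluster sum of squared errors (the k with the largest second
difference of the SSE curve).  Fitted clusters are ranked by activity level
— ascending centroid steps, ties broken by MVPA minutes — and each rank j
receives the achievement value j/(k-1), so k=3 yields {0, 0.5, 1}: these
values feed the cluster-based consistency target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "NUMERIC_FEATURES",
    "BINARY_FEATURE",
    "Normalizer",
    "fit_normalizer",
    "choose_k",
    "BehaviorClusterModel",
    "BehaviorClusterResults",
]

NUMERIC_FEATURES = ["light_min", "moderate_min", "vigorous_min", "steps"]
BINARY_FEATURE = "over_11k"
FEATURES = NUMERIC_FEATURES + [BINARY_FEATURE]


@dataclass
class Normalizer:
    """Invertible per-feature center/scale transform for the numeric features."""

    method: str
    center: pd.Series
    scale: pd.Series

    def transform(self, vectors: pd.DataFrame) -> np.ndarray:
        X = (vectors[NUMERIC_FEATURES] - self.center) / self.scale
        out = np.column_stack([X.to_numpy(), vectors[BINARY_FEATURE].astype(float).to_numpy()])
        return out

    def inverse_numeric(self, X: np.ndarray) -> pd.DataFrame:
        """Back-transform normalized numeric columns to original units."""
        back = X[:, : len(NUMERIC_FEATURES)] * self.scale.to_numpy() + self.center.to_numpy()
        return pd.DataFrame(back, columns=NUMERIC_FEATURES)


def fit_normalizer(vectors: pd.DataFrame, method: str = "zscore") -> Normalizer:
    """Fit a z-score or min-max normalizer on the numeric features.

    A constant feature gets unit scale (with a warning) so the transform
    stays invertible.
    """
    num = vectors[NUMERIC_FEATURES].astype(float)
    if method == "zscore":
        center = num.mean()
        scale = num.std(ddof=0)
    elif method == "minmax":
        center = num.min()
        scale = num.max() - num.min()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    constant = scale <= 0
    if constant.any():
        warnings.warn(
            f"constant feature(s) {list(scale.index[constant])}: using unit scale"
        )
        scale = scale.mask(constant, 1.0)
    return Normalizer(method=method, center=center, scale=scale)


def _sse_curve(X: np.ndarray, k_values: list[int], seed: int, n_restarts: int) -> pd.Series:
    sse = {}
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        sse[k] = float(km.inertia_)
    return pd.Series(sse, name="sse")


def choose_k(
    vectors: pd.DataFrame,
    k_range: tuple[int, int] = (1, 8),
    method: str = "zscore",
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, pd.Series]:
    """Elbow selection of the cluster count k.

    Fits k-means over ``k_range`` and returns the k maximizing the second
    difference of the SSE curve, SSE(k-1) - 2 SSE(k) + SSE(k+1) — the
    sharpest bend.  Ties go to the smallest k.  Also returns the SSE curve.
    Interior ks only are eligible; a too-large range is truncated to n-1
    with a warning.
    """
    lo, hi = k_range
    n = len(vectors)
    if hi >= n:
        warnings.warn(f"k_range upper bound {hi} >= n={n}; truncating to {n - 1}")
        hi = n - 1
    if lo < 1 or hi < lo + 2:
        raise ValueError("k_range must span at least three k values within [1, n-1]")
    norm = fit_normalizer(vectors, method)
    X = norm.transform(vectors)
    ks = list(range(lo, hi + 1))
    sse = _sse_curve(X, ks, seed, n_restarts)
    second_diff = {
        k: sse[k - 1] - 2 * sse[k] + sse[k + 1] for k in ks[1:-1]
    }
    best = max(sorted(second_diff), key=lambda k: second_diff[k])
    return best, sse


class BehaviorClusterModel:
    """K-means model of daily physical-activity behavior.

    Parameters
    ----------
    vectors : DataFrame
        Daily behavior vectors with columns ``light_min``, ``moderate_min``,
        ``vigorous_min``, ``steps``, ``over_11k`` (plus ``subject_id`` and
        ``date`` identifiers, carried through to the assignments).
    k : int or "auto"
        Number of clusters, or ``"auto"`` for elbow selection.
    normalization : {"zscore", "minmax"}
    order_key : {"steps", "composite"}
        Activity-ranking key: back-transformed centroid steps (default), or
        steps plus MVPA minutes.
    """

    def __init__(
        self,
        vectors: pd.DataFrame,
        k: int | str = 3,
        normalization: str = "zscore",
        order_key: str = "steps",
        k_range: tuple[int, int] = (1, 8),
        seed: int = 0,
        n_restarts: int = 10,
    ):
        missing = [c for c in FEATURES if c not in vectors.columns]
        if missing:
            raise ValueError(f"vectors missing feature column(s) {missing}")
        self.vectors = vectors.reset_index(drop=True)
        self.k = k
        self.normalization = normalization
        self.order_key = order_key
        self.k_range = k_range
        self.seed = seed
        self.n_restarts = n_restarts

    @classmethod
    def from_dataframe(cls, vectors: pd.DataFrame, **kwargs) -> "BehaviorClusterModel":
        return cls(vectors, **kwargs)

    def fit(self) -> "BehaviorClusterResults":
        sse_curve = None
        if self.k == "auto":
            k, sse_curve = choose_k(
                self.vectors, self.k_range, self.normalization, self.seed, self.n_restarts
            )
        else:
            k = int(self.k)
        if len(self.vectors) < k:
            raise ValueError(f"need at least k={k} vectors, have {len(self.vectors)}")
        normalizer = fit_normalizer(self.vectors, self.normalization)
        X = normalizer.transform(self.vectors)
        km = KMeans(n_clusters=k, n_init=self.n_restarts, random_state=self.seed).fit(X)
        return BehaviorClusterResults(self, k, normalizer, km, sse_curve)


class BehaviorClusterResults:
    """Fitted behavior clusters with activity ranks and achievement values.

    Clusters are relabelled so that the cluster index equals the activity
    rank: cluster 0 is the least active and cluster k-1 the most active, and
    cluster j's achievement value is j/(k-1) (0.5 exactly for the middle of
    three).  ``centroids`` are in original units; ``centroids_normalized``
    in the fitting space.
    """

    def __init__(self, model, k, normalizer, kmeans, sse_curve=None):
        self.model = model
        self.k = k
        self.normalizer = normalizer
        self.sse_curve = sse_curve
        self.sse = float(kmeans.inertia_)

        raw_centroids = normalizer.inverse_numeric(kmeans.cluster_centers_)
        raw_centroids[BINARY_FEATURE] = kmeans.cluster_centers_[:, len(NUMERIC_FEATURES)]
        order = self._activity_order(raw_centroids, model.order_key)
        # rank[c] = activity rank of original k-means label c
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)

        self.labels_ = rank[kmeans.labels_]
        self.centroids = raw_centroids.iloc[order].reset_index(drop=True)
        self.centroids_normalized = kmeans.cluster_centers_[order]
        self.values = np.arange(k) / (k - 1) if k > 1 else np.array([1.0])
        self.cluster_sizes = np.bincount(self.labels_, minlength=k)

    @staticmethod
    def _activity_order(centroids: pd.DataFrame, order_key: str) -> np.ndarray:
        steps = centroids["steps"].to_numpy()
        mvpa = (centroids["moderate_min"] + centroids["vigorous_min"]).to_numpy()
        if order_key == "steps":
            key = np.stack([steps, mvpa])
        elif order_key == "composite":
            key = np.stack([steps + mvpa, mvpa])
        else:
            raise ValueError(f"unknown order_key {order_key!r}")
        return np.lexsort(key[::-1])

    def assignments(self) -> pd.DataFrame:
        """Per subject-day cluster, rank and achievement value."""
        out = self.model.vectors[["subject_id", "date"]].copy()
        out["cluster"] = self.labels_
        out["rank"] = self.labels_
        out["value"] = self.values[self.labels_]
        return out

    def cluster_values(self) -> dict[int, float]:
        return {j: float(v) for j, v in enumerate(self.values)}

    def centroid_table(self) -> pd.DataFrame:
        """Centroid table in original units, one row per cluster by rank,
        with the step-goal majority flag and member counts."""
        tab = self.centroids.copy()
        tab.insert(0, "cluster", np.arange(self.k))
        tab["over_11k_majority"] = tab[BINARY_FEATURE] > 0.5
        tab["n"] = self.cluster_sizes
        tab["value"] = self.values
        return tab.drop(columns=[BINARY_FEATURE])

    def summary(self) -> str:
        lines = [
            "Daily behavior clustering (k-means)",
            "===================================",
            f"k = {self.k}   n = {len(self.model.vectors)} subject-days   "
            f"SSE = {self.sse:.2f}   normalization = {self.normalizer.method}",
            "",
            self.centroid_table().round(2).to_string(index=False),
        ]
        if self.sse_curve is not None:
            lines += ["", "elbow SSE curve:", self.sse_curve.round(2).to_string()]
        return "\n".join(lines)
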