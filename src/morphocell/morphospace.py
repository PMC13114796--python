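"""Morphospace construction: normalisation, morphotype clustering, projection.

Cells described by the six shape descriptors are z-scored, clustered with
k-means into morphotypes (T1 round, T2 droplet, T3 spindle for k = 3),
projected by PCA, optionally embedded in 2-D with t-SNE, and categorised by
aspect ratio into M1/M2/M3 bins.

Cluster labels are canonicalised by ascending centroid aspect ratio so that
T1 is always the roundest group regardless of the k-means seed, making runs
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.utils.validation import check_is_fitted

from .shape_descriptors import DESCRIPTOR_COLUMNS

__all__ = [
    "FeatureZScorer",
    "MorphotypeKMeans",
    "MorphospacePCA",
    "MorphospaceResult",
    "normalize_features",
    "cluster_kmeans",
    "pca_project",
    "embed_2d",
    "AspectRatioCategorizer",
    "classify_aspect_ratio",
    "composition_table",
    "build_morphospace",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        cols = [c for c in DESCRIPTOR_COLUMNS if c in table.columns]
        if len(cols) == len(DESCRIPTOR_COLUMNS):
            return table[cols].to_numpy(dtype=float), cols
        return table.to_numpy(dtype=float), list(table.columns)
    X = np.asarray(table, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


class FeatureZScorer(BaseEstimator, TransformerMixin):
    """Per-column z-scoring with the sample (n−1) standard deviation.

    Stores ``mean_`` and ``scale_`` for the inverse transform.  A constant
    column cannot be scaled and raises, naming the offending column.
    """

    def __init__(self, ddof: int = 1) -> None:
        self.ddof = ddof

    def fit(self, X, y=None):
        M, cols = _as_matrix(X)
        if M.shape[0] < 2:
            raise ValueError("need at least 2 rows to z-score")
        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=self.ddof)
        zero = np.flatnonzero(self.scale_ == 0)
        if zero.size:
            raise ValueError(f"constant column(s): {[cols[i] for i in zero]}")
        self.columns_ = cols
        self.n_features_in_ = M.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        M, _ = _as_matrix(X)
        return (M - self.mean_) / self.scale_

    def inverse_transform(self, Z) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_


class MorphotypeKMeans(BaseEstimator, ClusterMixin):
    """k-means morphotyping with canonical label order.

    Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by
    inertia, deterministic given ``random_state``.  After fitting, labels
    are renumbered 0..k−1 by ascending centroid value in the
    ``order_feature`` column (aspect ratio by default), so label 0 is always
    the roundest morphotype.

    Attributes (after fit): ``cluster_centers_``, ``labels_``, ``inertia_``.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_restarts: int = 10,
        random_state: int | None = 0,
        order_feature: int | str = "aspect_ratio",
    ) -> None:
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.order_feature = order_feature

    def fit(self, X, y=None):
        M, cols = _as_matrix(X)
        if self.n_clusters > M.shape[0]:
            raise ValueError(
                f"k={self.n_clusters} exceeds the number of rows {M.shape[0]}"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=self.random_state,
        ).fit(M)
        if isinstance(self.order_feature, str):
            j = cols.index(self.order_feature) if self.order_feature in cols else 0
        else:
            j = int(self.order_feature)
        order = np.argsort(km.cluster_centers_[:, j], kind="stable")
        relabel = np.empty(self.n_clusters, dtype=int)
        relabel[order] = np.arange(self.n_clusters)
        self.cluster_centers_ = km.cluster_centers_[order]
        self.labels_ = relabel[km.labels_]
        self.inertia_ = float(km.inertia_)
        self.columns_ = cols
        self.n_features_in_ = M.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        M, _ = _as_matrix(X)
        d = ((M[:, None, :] - self.cluster_centers_[None]) ** 2).sum(-1)
        return np.argmin(d, axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


class MorphospacePCA(BaseEstimator, TransformerMixin):
    """PCA of the descriptor covariance with a deterministic sign convention.

    Components are the eigenvectors of the feature covariance; the sign of
    each is fixed so its largest-|loading| entry is positive, making runs
    reproducible.  On rank-deficient data only the components up to the
    numerical rank are returned, with a warning.

    Attributes: ``loadings_`` (features × components), ``explained_variance_ratio_``,
    ``mean_``.
    """

    def __init__(self, n_components: int = 2) -> None:
        self.n_components = n_components

    def fit(self, X, y=None):
        M, cols = _as_matrix(X)
        if M.shape[0] < 3:
            raise ValueError("need at least 3 rows for PCA")
        rank = np.linalg.matrix_rank(M - M.mean(0))
        n_comp = min(self.n_components, rank, M.shape[1])
        if n_comp < self.n_components:
            import warnings

            warnings.warn(
                f"rank-deficient matrix: returning {n_comp} component(s)",
                stacklevel=2,
            )
        pca = PCA(n_components=n_comp, svd_solver="full").fit(M)
        comps = pca.components_.copy()
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.loadings_ = comps.T
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.explained_variance_ = pca.explained_variance_
        self.columns_ = cols
        self.n_features_in_ = M.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        M, _ = _as_matrix(X)
        return (M - self.mean_) @ self.loadings_


class AspectRatioCategorizer(BaseEstimator):
    """Assign M1/M2/M3 shape categories from the aspect ratio alone.

    ``thresholds=None`` (default) uses the fitted population's tertiles;
    otherwise pass a fixed pair ``(a1, a2)`` with a1 < a2.  The bins are
    M1: AR < a1, M2: a1 ≤ AR < a2, M3: AR ≥ a2 (right-closed at a2).
    """

    CATEGORIES = ("M1", "M2", "M3")

    def __init__(self, thresholds: tuple[float, float] | None = None) -> None:
        self.thresholds = thresholds

    def fit(self, X, y=None):
        ar = self._aspect_ratios(X)
        if self.thresholds is not None:
            a1, a2 = self.thresholds
            if not a1 < a2:
                raise ValueError("thresholds must satisfy a1 < a2")
            self.thresholds_ = (float(a1), float(a2))
        else:
            self.thresholds_ = tuple(np.quantile(ar, [1 / 3, 2 / 3]).tolist())
        return self

    @staticmethod
    def _aspect_ratios(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X["aspect_ratio"].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X if X.ndim == 1 else X[:, 0]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        ar = self._aspect_ratios(X)
        a1, a2 = self.thresholds_
        idx = np.where(ar < a1, 0, np.where(ar < a2, 1, 2))
        return np.array(self.CATEGORIES)[idx]

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


@dataclass
class MorphospaceResult:
    """Bundle of everything the morphospace pipeline produced for one table."""

    normalized_matrix: np.ndarray
    cluster_labels: np.ndarray  # 1-based morphotype index (T1..Tk)
    cluster_centroids: np.ndarray
    inertia: float
    pca_loadings: np.ndarray
    pca_scores: np.ndarray
    explained_variance: np.ndarray
    embedding: np.ndarray
    seed: int
    feature_columns: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def normalize_features(table, ddof: int = 1):
    """Z-score each descriptor column; returns (matrix, fitted scaler)."""
    scaler = FeatureZScorer(ddof=ddof).fit(table)
    return scaler.transform(table), scaler


def cluster_kmeans(matrix, k: int = 3, seed: int = 0, n_restarts: int = 10,
                   order_feature: int | str = 0):
    """Best-of-restarts k-means; returns (labels, centroids, inertia)."""
    est = MorphotypeKMeans(
        n_clusters=k, n_restarts=n_restarts, random_state=seed,
        order_feature=order_feature,
    ).fit(matrix)
    return est.labels_, est.cluster_centers_, est.inertia_


def pca_project(matrix, n_components: int = 2):
    """PCA; returns (loadings, scores, explained_variance_ratio)."""
    est = MorphospacePCA(n_components=n_components).fit(matrix)
    return est.loadings_, est.transform(matrix), est.explained_variance_ratio_


def embed_2d(matrix, method: str = "tsne", seed: int = 0,
             perplexity: float = 30.0, n_iter: int = 1000) -> np.ndarray:
    """2-D embedding for visualisation: seeded t-SNE or plain PCA scores."""
    M, _ = _as_matrix(matrix)
    if method == "pca":
        _, scores, _ = pca_project(M, n_components=2)
        return scores
    if method == "tsne":
        if M.shape[0] < 5:
            raise ValueError("t-SNE needs at least 5 rows")
        perp = min(perplexity, (M.shape[0] - 1) / 3.0)
        ts = TSNE(
            n_components=2,
            perplexity=perp,
            max_iter=n_iter,
            init="pca",
            random_state=seed,
        )
        return ts.fit_transform(M)
    raise ValueError(f"unknown embedding method: {method!r}")


def classify_aspect_ratio(table, thresholds: tuple[float, float] | None = None) -> pd.DataFrame:
    """Categorise cells into M1/M2/M3 by aspect ratio.

    ``thresholds=None`` uses population tertiles.  Returns a DataFrame with
    cell_id (when available), category, and the thresholds used.
    """
    cat = AspectRatioCategorizer(thresholds)
    labels = cat.fit_predict(table)
    a1, a2 = cat.thresholds_
    out = pd.DataFrame({"category": labels})
    if isinstance(table, pd.DataFrame) and "cell_id" in table.columns:
        out.insert(0, "cell_id", table["cell_id"].to_numpy())
    out["threshold_low"] = a1
    out["threshold_high"] = a2
    return out


def composition_table(categories, group_labels) -> pd.DataFrame:
    """Fraction of cells per category within each group; rows sum to 1.

    An empty group yields a NaN row with a warning.
    """
    import warnings

    categories = np.asarray(categories)
    group_labels = np.asarray(group_labels)
    if categories.shape != group_labels.shape:
        raise ValueError("categories and group_labels must have equal length")
    cats = sorted(np.unique(categories).tolist())
    groups = sorted(np.unique(group_labels).tolist())
    rows = {}
    for g in groups:
        sel = categories[group_labels == g]
        if sel.size == 0:  # pragma: no cover - unique() precludes this path
            warnings.warn(f"group {g!r} is empty", stacklevel=2)
            rows[g] = [np.nan] * len(cats)
        else:
            rows[g] = [(sel == c).mean() for c in cats]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cats)


def build_morphospace(
    table: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    embed_method: str = "tsne",
) -> MorphospaceResult:
    """Run the full normalise → cluster → PCA → embed pipeline on a table."""
    Z, scaler = normalize_features(table)
    ar_index = scaler.columns_.index("aspect_ratio") if "aspect_ratio" in scaler.columns_ else 0
    labels, centroids, inertia = cluster_kmeans(
        Z, k=k, seed=seed, n_restarts=n_restarts, order_feature=ar_index
    )
    loadings, scores, evr = pca_project(Z)
    embedding = embed_2d(Z, method=embed_method, seed=seed)
    return MorphospaceResult(
        normalized_matrix=Z,
        cluster_labels=labels + 1,  # report as T1..Tk
        cluster_centroids=centroids,
        inertia=inertia,
        pca_loadings=loadings,
        pca_scores=scores,
        explained_variance=evr,
        embedding=embedding,
        seed=seed,
        feature_columns=scaler.columns_,
    )
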