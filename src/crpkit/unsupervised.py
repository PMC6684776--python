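"""Unsupervised exploration: PCA with T²/Q outlier limits, Ward HCA.

PCA is fitted by SVD of the column-centered matrix.  Outlier screening uses
the two complementary distances of a PCA projection: Hotelling's T² (the
within-model Mahalanobis distance of the scores) and Q (the squared
off-model reconstruction residual).  Control limits at a confidence level
(default 95%) come from the F-distribution scaling for T² and the
Jackson-Mudholkar approximation for Q; a sample is flagged only when BOTH
statistics exceed their limits — the conjunctive rule used when screening
fingerprint matrices before classification.

Hierarchical clustering is agglomerative Ward linkage on squared Euclidean
distances (scipy's linkage does the merging; merge heights are reported on
the squared-Euclidean scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .io import FingerprintMatrix

__all__ = [
    "PcaModel",
    "OutlierReport",
    "Dendrogram",
    "fit_pca",
    "pca_transform",
    "t2_q_outliers",
    "hca_ward",
    "cut_dendrogram",
    "dendrogram_to_newick",
]


@dataclass
class PcaModel:
    n_components: int
    mean_: np.ndarray            # column means (p,)
    loadings: np.ndarray         # (p, k), orthonormal columns
    scores: np.ndarray           # (n, k) training scores
    explained_variance: np.ndarray   # per-component score variance (ddof=1)
    eigenvalues_all: np.ndarray  # all nonzero-rank eigenvalues, for Q limits
    n_samples: int

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.eigenvalues_all.sum()


@dataclass
class OutlierReport:
    sample_ids: list[str]
    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    confidence: float
    flagged: list[str]


def fit_pca(m: FingerprintMatrix | np.ndarray, n_components: int) -> PcaModel:
    """Centered-SVD PCA with a deterministic sign convention.

    Each loading column is flipped so its largest-magnitude element is
    positive, making score plots reproducible across runs and platforms.
    """
    X = m.X if isinstance(m, FingerprintMatrix) else np.asarray(m, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}] for a {n}x{p} matrix")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = (s ** 2) / (n - 1)
    V = Vt[:n_components].T  # (p, k)
    # sign convention: largest-|loading| element positive per component
    for k in range(n_components):
        idx = np.argmax(np.abs(V[:, k]))
        if V[idx, k] < 0:
            V[:, k] = -V[:, k]
    scores = Xc @ V
    return PcaModel(
        n_components=n_components,
        mean_=mean,
        loadings=V,
        scores=scores,
        explained_variance=eigenvalues[:n_components],
        eigenvalues_all=eigenvalues[:max_rank],
        n_samples=n,
    )


def pca_transform(model: PcaModel, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - model.mean_) @ model.loadings


def _t2_limit(k: int, n: int, confidence: float) -> float:
    if n <= k:
        return np.inf
    f = stats.f.ppf(confidence, k, n - k)
    return k * (n - 1) / (n - k) * f


def _q_limit(residual_eigenvalues: np.ndarray, confidence: float) -> float:
    """Jackson-Mudholkar approximate upper control limit for Q."""
    lam = residual_eigenvalues[residual_eigenvalues > 1e-30]
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = lam.sum(), (lam ** 2).sum(), (lam ** 3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
    if h0 <= 0:
        h0 = 1e-4
    ca = stats.norm.ppf(confidence)
    term = ca * np.sqrt(2.0 * th2 * h0 ** 2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1 ** 2
    if term <= 0:
        return 0.0
    return float(th1 * term ** (1.0 / h0))


def t2_q_outliers(model: PcaModel, m: FingerprintMatrix | np.ndarray,
                  confidence: float = 0.95,
                  sample_ids: list[str] | None = None) -> OutlierReport:
    """Score samples against a PCA model; flag those with BOTH T² and Q high.

    T²_i = sum_k t_ik² / lambda_k with lambda the calibration score
    variances; Q_i is the squared residual after projecting onto the model
    plane.  Limits are at ``confidence`` (default 0.95).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if isinstance(m, FingerprintMatrix):
        X = m.X
        ids = sample_ids if sample_ids is not None else list(m.sample_ids)
    else:
        X = np.asarray(m, dtype=float)
        ids = sample_ids if sample_ids is not None else [str(i) for i in range(X.shape[0])]
    if X.shape[1] != model.mean_.size:
        raise ValueError("matrix columns do not match the PCA model")
    Xc = X - model.mean_
    T = Xc @ model.loadings
    lam = model.explained_variance
    t2 = np.einsum("ik,ik->i", T / lam, T)
    resid = Xc - T @ model.loadings.T
    q = np.einsum("ij,ij->i", resid, resid)
    t2_lim = _t2_limit(model.n_components, model.n_samples, confidence)
    q_lim = _q_limit(model.eigenvalues_all[model.n_components:], confidence)
    flagged_mask = (t2 > t2_lim) & (q > q_lim)
    flagged = [ids[i] for i in np.where(flagged_mask)[0]]
    return OutlierReport(sample_ids=ids, t2=t2, q=q, t2_limit=float(t2_lim),
                         q_limit=float(q_lim), confidence=confidence, flagged=flagged)


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``linkage`` is the scipy-format (n-1, 4) matrix whose third column is
    the Euclidean Ward distance; ``merge_heights`` exposes those heights on
    the squared-Euclidean scale used throughout this toolkit.
    """

    linkage: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] ** 2

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h * h), int(size))
                for a, b, h, size in self.linkage]


def hca_ward(m: FingerprintMatrix | np.ndarray,
             leaf_labels: list[str] | None = None) -> Dendrogram:
    """Ward-linkage agglomerative clustering of the rows."""
    if isinstance(m, FingerprintMatrix):
        X = m.X
        labels = leaf_labels if leaf_labels is not None else list(m.sample_ids)
    else:
        X = np.asarray(m, dtype=float)
        labels = leaf_labels if leaf_labels is not None else [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, leaf_labels=labels)


def cut_dendrogram(d: Dendrogram, k: int | None = None,
                   height: float | None = None) -> np.ndarray:
    """Flat cluster labels per leaf, by cluster count or by merge height.

    Exactly one of ``k`` (number of clusters) or ``height`` (keep merges
    whose squared-Euclidean height is <= cutoff) must be given.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= d.n_leaves:
            raise ValueError(f"k must be in [1, {d.n_leaves}]")
        return hierarchy.fcluster(d.linkage, t=k, criterion="maxclust")
    if height < 0:
        raise ValueError("height must be >= 0")
    return hierarchy.fcluster(d.linkage, t=float(np.sqrt(height)), criterion="distance")


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Nested-parenthesis (Newick) rendering with branch lengths from merge
    heights, for external plotting tools."""
    tree = hierarchy.to_tree(d.linkage)

    def fmt(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{d.leaf_labels[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return fmt(tree, tree.dist) + ";"
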