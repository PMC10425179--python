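"""Multivariate analyses of receptor fingerprints.

Areas are compared as points in z-scored 14-receptor fingerprint space:
Euclidean distances capture differences in both the size and the shape of
fingerprints; Ward agglomeration with cophenetic validation builds the
hierarchical grouping; a permutation-calibrated k-means criterion picks the
highest acceptable number of clusters; PCA projects the 14-dimensional
space to two components for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import norm, pearsonr
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class Dendrogram:
    """Ward merge sequence with leaf labels (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Export as a Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.linkage):
            i, j = int(i), int(j)
            bi = h - heights[i]
            bj = h - heights[j]
            nodes[n + k] = f"({nodes[i]}:{bi:.6g},{nodes[j]}:{bj:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def fingerprint_distance(a, b) -> float:
    """Euclidean distance between two (normalized) fingerprints."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    return float(np.linalg.norm(a - b))


def _as_matrix(matrix) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrix, pd.DataFrame):
        labels = tuple(str(i) for i in matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = tuple(f"obs{i}" for i in range(x.shape[0]))
    if np.isnan(x).any():
        raise ValueError("fingerprint matrix must have no missing cells")
    return x, labels


def ward_cluster(matrix) -> Dendrogram:
    """Agglomerative Ward dendrogram on Euclidean fingerprint distances."""
    x, labels = _as_matrix(matrix)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 areas")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate area labels")
    z = hierarchy.linkage(x, method="ward")
    return Dendrogram(z, labels)


def cophenetic_correlation(dend: Dendrogram, matrix) -> float:
    """Pearson correlation between input and dendrogram (cophenetic) distances."""
    x, _ = _as_matrix(matrix)
    if x.shape[0] < 3:
        raise ValueError("cophenetic correlation needs at least 3 areas")
    coph = hierarchy.cophenet(dend.linkage)
    r, _ = pearsonr(pdist(x), coph)
    return float(r)


def linkage_comparison(matrix, methods=("ward", "single", "complete", "average")) -> pd.Series:
    """Cophenetic coefficient of several linkage methods on the same data."""
    x, labels = _as_matrix(matrix)
    out = {}
    for m in methods:
        z = hierarchy.linkage(x, method=m)
        coph = hierarchy.cophenet(z)
        out[m] = float(pearsonr(pdist(x), coph)[0])
    return pd.Series(out)


@dataclass(frozen=True)
class KSelection:
    """Outcome of the permutation-calibrated cluster-count search."""

    k: int
    table: pd.DataFrame  # per k: log_w, gap, gap_se, increment z-threshold pass


def _log_w(x: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator) -> float:
    if k == 1:
        return float(np.log(np.sum((x - x.mean(axis=0)) ** 2)))
    km = KMeans(n_clusters=k, n_init=n_restarts,
                random_state=int(rng.integers(2 ** 31)))
    km.fit(x)
    return float(np.log(max(km.inertia_, 1e-300)))


def kmeans_select(matrix, k_range=range(2, 7), n_permutations: int = 999,
                  seed: int = 0, n_restarts: int = 100,
                  level: float = 0.95) -> KSelection:
    """Highest acceptable number of k-means clusters via a permutation null.

    For each k (including the k=1 baseline) the within-cluster dispersion
    W_k is compared with its distribution over ``n_permutations`` datasets
    whose columns are shuffled independently (destroying joint structure,
    keeping marginals), giving a gap score mean_perm(log W_k) - log W_k.
    k is *acceptable* when every gap increment from 2..k exceeds
    z(level) * SE of the permuted gap; the selection is the largest
    acceptable k, or 1 when no k in ``k_range`` is supported.
    """
    x, _ = _as_matrix(matrix)
    k_range = sorted(int(k) for k in k_range)
    if not k_range or k_range[0] < 2 or k_range[-1] > x.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_areas - 1]")
    rng = np.random.default_rng(seed)
    ks = [1] + k_range
    log_w = {k: _log_w(x, k, n_restarts, rng) for k in ks}
    null_log_w = {k: np.empty(n_permutations) for k in ks}
    for b in range(n_permutations):
        xp = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
        for k in ks:
            null_log_w[k][b] = _log_w(xp, k, n_restarts, rng)
    gap = {k: float(null_log_w[k].mean() - log_w[k]) for k in ks}
    se = {k: float(null_log_w[k].std(ddof=1) * np.sqrt(1 + 1 / n_permutations))
          for k in ks}
    z = norm.ppf(level)
    rows = []
    supported = {}
    for k_prev, k in zip(ks, ks[1:]):
        incr = gap[k] - gap[k_prev]
        supported[k] = incr > z * se[k]
        rows.append((k, log_w[k], gap[k], se[k], incr, supported[k]))
    best = 1
    for k in k_range:
        if supported[k]:
            best = k
        else:
            break
    table = pd.DataFrame(rows, columns=["k", "log_w", "gap", "gap_se",
                                        "gap_increment", "supported"])
    return KSelection(k=best, table=table)


def pca(matrix, n_components: int | None = None):
    """PCA of the column-centred fingerprint matrix.

    Returns (loadings, scores, explained variance fractions); the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    x, _ = _as_matrix(matrix)
    n, p = x.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 areas")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("rank-0 matrix: all areas identical")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    k = n_components or min(n - 1, p)
    loadings = vt[:k].T               # p x k
    scores = u[:, :k] * s[:k]         # n x k
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores, frac[:k]
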