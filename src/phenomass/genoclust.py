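"""Genotype clustering: compress a high-dimensional marker matrix to
cluster IDs via PCA, k-means and elbow selection of k.

The projection keeps the first ``n_components`` principal components of the
column-centred marker matrix (markers share a biallelic 0/1/2 coding, so
columns are not variance-scaled).  k-means is run over a range of k; the
within-cluster sum of squares (WCSS) curve is screened with a
max-perpendicular-distance elbow rule, and the final assignment is
relabelled canonically (descending cluster size, ties by centroid norm) so
that two runs reaching the same partition emit identical IDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .trialsim import MarkerMatrix

__all__ = [
    "ClusterAssignment",
    "marker_pca",
    "wcss_curve",
    "elbow_select",
    "cluster_genotypes",
    "cluster_markers",
]


@dataclass
class ClusterAssignment:
    """Hybrid -> cluster ID (1..k) plus the WCSS curve used to choose k."""

    assignment: dict[str, int]
    k: int
    k_range: list[int]
    wcss: list[float]
    projection: np.ndarray
    seed: int
    no_elbow: bool = False
    degenerate_ks: list[int] | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array(list(self.assignment.values()))


def marker_pca(markers: MarkerMatrix, n_components: int = 10) -> np.ndarray:
    """Column-centred PCA projection of the marker matrix.

    Components are ordered by variance with a deterministic sign convention
    (largest-magnitude loading of each component positive).
    """
    X = np.asarray(markers.values, dtype=float)
    n, m = X.shape
    if n_components > min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(hybrids-1, markers)="
            f"{min(n - 1, m)}")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        return np.zeros((n, n_components))
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(Xc)
    comp = pca.components_
    for j in range(comp.shape[0]):
        i = int(np.argmax(np.abs(comp[j])))
        if comp[j, i] < 0:
            proj[:, j] = -proj[:, j]
    return proj


def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-n_init k-means (k-means++ seeding, Lloyd iterations)."""
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        # degenerate: every distinct point its own centre, WCSS of that
        # solution (0), flagged by the caller
        km = KMeans(n_clusters=n_distinct, n_init=n_init, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = km.fit_predict(X)
        return labels, km.cluster_centers_, float(km.inertia_)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, float(km.inertia_)


def wcss_curve(projection: np.ndarray, k_range, seed: int = 0,
               n_init: int = 10) -> tuple[list[int], list[float], list[int]]:
    """WCSS per k (best of ``n_init`` restarts); returns (ks, wcss, degenerate).

    ``degenerate`` lists the k values exceeding the number of distinct
    points, for which the zero-WCSS degenerate solution is reported.
    """
    X = np.asarray(projection, dtype=float)
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 1 or ks[-1] > len(X):
        raise ValueError("k_range must lie within [1, n_points]")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    wcss, degenerate = [], []
    for k in ks:
        if k == 1:
            wcss.append(float(((X - X.mean(axis=0)) ** 2).sum()))
            continue
        _, _, inertia = _kmeans(X, k, seed, n_init)
        wcss.append(inertia)
        if k > n_distinct:
            degenerate.append(k)
    # enforce monotonicity against k-means local optima: a larger k can
    # always reproduce a smaller k's partition
    for i in range(1, len(wcss)):
        wcss[i] = min(wcss[i], wcss[i - 1])
    return ks, wcss, degenerate


def elbow_select(ks, wcss) -> tuple[int, bool]:
    """Elbow of a WCSS curve: the k whose point is farthest from the chord
    joining the curve's endpoints; ties toward smaller k.

    Returns ``(k, no_elbow)``; a (numerically) straight curve yields the
    smallest k with ``no_elbow=True``.
    """
    ks = np.asarray(list(ks), dtype=float)
    w = np.asarray(list(wcss), dtype=float)
    if len(ks) < 4:
        raise ValueError("elbow selection needs a curve over >= 4 k values")
    p0 = np.array([ks[0], w[0]])
    p1 = np.array([ks[-1], w[-1]])
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        return int(ks[0]), True
    # perpendicular distance via the 2-D cross product
    v = np.column_stack([ks - p0[0], w - p0[1]])
    dist = np.abs(d[0] * v[:, 1] - d[1] * v[:, 0]) / norm
    scale = max(np.abs(w).max(), 1.0)
    if dist.max() <= 1e-9 * scale:
        return int(ks[0]), True
    return int(ks[int(np.argmax(dist))]), False


def _canonical_relabel(labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending size, ties by centroid norm."""
    ids = np.unique(labels)
    sizes = {i: int(np.sum(labels == i)) for i in ids}
    norms = {i: float(np.linalg.norm(centers[i])) for i in ids}
    order = sorted(ids, key=lambda i: (-sizes[i], -norms[i], i))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def cluster_genotypes(projection: np.ndarray, k: int,
                      hybrid_ids: list[str], seed: int = 0,
                      n_init: int = 10, k_range=None, wcss=None,
                      no_elbow: bool = False) -> ClusterAssignment:
    """Final k-means assignment at the chosen k, canonically relabelled."""
    X = np.asarray(projection, dtype=float)
    if not (1 <= k <= len(X)):
        raise ValueError("k must be in [1, n_hybrids]")
    if k == 1:
        labels = np.ones(len(X), dtype=int)
        wcss_k = [float(((X - X.mean(axis=0)) ** 2).sum())]
        return ClusterAssignment(dict(zip(hybrid_ids, labels.tolist())), 1,
                                 list(k_range or [1]), list(wcss or wcss_k),
                                 X, seed, no_elbow)
    raw, centers, _ = _kmeans(X, k, seed, n_init)
    labels = _canonical_relabel(raw, centers)
    return ClusterAssignment(dict(zip(hybrid_ids, labels.tolist())),
                             int(labels.max()), list(k_range or []),
                             list(wcss or []), X, seed, no_elbow)


def cluster_markers(markers: MarkerMatrix, n_components: int = 10,
                    k_max: int = 10, seed: int = 0,
                    n_init: int = 10) -> ClusterAssignment:
    """End-to-end genotype clustering: PCA -> WCSS scan -> elbow -> k-means."""
    proj = marker_pca(markers, n_components)
    ks, wcss, degenerate = wcss_curve(proj, range(1, k_max + 1), seed, n_init)
    k, no_elbow = elbow_select(ks, wcss)
    out = cluster_genotypes(proj, k, markers.hybrid_ids, seed, n_init,
                            k_range=ks, wcss=wcss, no_elbow=no_elbow)
    out.degenerate_ks = degenerate
    return out
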