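"""Unsupervised stage: PCA with contribution decomposition, hierarchical and
partitioning clustering, elbow / cluster-transition diagnostics, Mahalanobis
distances from a marker-subspace centroid.

Samples are the observations and genes the variables throughout (the transpose
mode is available via ``transpose=True`` where it makes sense).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, ValidationError

__all__ = [
    "PcaResult",
    "ClusteringResult",
    "MahalanobisReport",
    "pca_decompose",
    "hierarchical_cluster",
    "kmeans_partition",
    "pam_partition",
    "elbow_profile",
    "clustree_transitions",
    "mahalanobis_from_centroid",
]


@dataclass(frozen=True)
class PcaResult:
    """SVD-based PCA of the (centered, optionally scaled) samples x genes matrix."""

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    scores: np.ndarray                 # samples x PCs
    loadings: np.ndarray               # genes x PCs, unit columns
    explained_variance_pct: np.ndarray  # per PC, sums to 100
    contributions_pct: np.ndarray      # genes x PCs, each column sums to 100

    def contributions_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.contributions_pct.shape[1])]
        return pd.DataFrame(self.contributions_pct, index=list(self.gene_ids),
                            columns=cols)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.sample_ids), columns=cols)


@dataclass
class ClusteringResult:
    """Shared contract for hierarchical and partitioning clustering.

    assignments maps k -> integer labels (0-based) over samples in matrix order;
    wss maps k -> total within-cluster sum of squares in the clustered space.
    merges is the scipy linkage matrix for hierarchical results, else None.
    """

    method: str
    sample_ids: tuple[str, ...]
    assignments: dict[int, np.ndarray]
    wss: dict[int, float] = field(default_factory=dict)
    merges: np.ndarray | None = None

    def labels(self, k: int) -> np.ndarray:
        if k not in self.assignments:
            raise ValidationError(f"no assignment stored for k={k}")
        return self.assignments[k]


@dataclass(frozen=True)
class MahalanobisReport:
    sample_ids: tuple[str, ...]
    genes: tuple[str, ...]
    distances: np.ndarray
    covariance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": list(self.sample_ids),
                             "mahalanobis": self.distances})


def _obs_matrix(x: ExpressionMatrix, transpose: bool) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Return (observations x variables, obs ids, var ids)."""
    if transpose:
        return x.values, x.gene_ids, x.sample_ids
    return x.values.T, x.sample_ids, x.gene_ids


def pca_decompose(x: ExpressionMatrix, scale: bool = True,
                  transpose: bool = False) -> PcaResult:
    """PCA by singular-value decomposition of the centered (and scaled) matrix.

    contributions_pct(g, PC) = 100 * loading(g, PC)^2 / sum_g loading(g, PC)^2.
    Scaling divides each variable by its sample (n-1) sd, as R's prcomp does.
    """
    mat, obs_ids, var_ids = _obs_matrix(x, transpose)
    n_obs, n_var = mat.shape
    if n_obs < 2 or n_var < 2:
        raise ValidationError("PCA requires >= 2 samples and >= 2 genes")
    centered = mat - mat.mean(axis=0, keepdims=True)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = var_ids[int(np.argmax(sd == 0))]
            raise ValidationError(
                f"variable {bad!r} has zero variance; cannot scale (set scale=False)"
            )
        centered = centered / sd
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC is positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    loadings = vt.T
    var = s ** 2
    explained = 100.0 * var / var.sum()
    contrib = 100.0 * loadings ** 2 / (loadings ** 2).sum(axis=0, keepdims=True)
    return PcaResult(obs_ids, var_ids, scores, loadings, explained, contrib)


def _wss(mat: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = mat[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def hierarchical_cluster(x: ExpressionMatrix, distance: str = "one_minus_pearson",
                         linkage: str = "average", transpose: bool = False,
                         k_range: range | None = None) -> ClusteringResult:
    """Agglomerative clustering of samples with full merge history.

    distance ``one_minus_pearson`` is 1 - Pearson r between observation
    vectors; ``euclidean`` is also supported. Cutting the tree at any
    1 <= k <= n yields exactly k clusters.
    """
    mat, obs_ids, _ = _obs_matrix(x, transpose)
    n = mat.shape[0]
    if n < 2:
        raise ValidationError("clustering requires >= 2 observations")
    if distance == "one_minus_pearson":
        sd = mat.std(axis=1)
        if np.any(sd == 0):
            bad = obs_ids[int(np.argmax(sd == 0))]
            raise ValidationError(
                f"observation {bad!r} is constant; Pearson distance undefined"
            )
        dist = pdist(mat, metric="correlation")
    elif distance == "euclidean":
        dist = pdist(mat, metric="euclidean")
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    merges = hierarchy.linkage(dist, method=linkage)
    ks = list(k_range) if k_range is not None else list(range(1, n + 1))
    assignments: dict[int, np.ndarray] = {}
    inner_ks = [k for k in ks if k < n]
    if inner_ks:
        cuts = hierarchy.cut_tree(merges, n_clusters=inner_ks)
        assignments.update({k: cuts[:, i].astype(int)
                            for i, k in enumerate(inner_ks)})
    if n in ks:  # scipy's cut_tree mishandles n_clusters == n
        assignments[n] = np.arange(n)
    wss = {k: _wss(mat, lab) for k, lab in assignments.items()}
    return ClusteringResult("hierarchical", obs_ids, assignments, wss, merges)


def kmeans_partition(x: ExpressionMatrix, k: int, n_init: int = 25,
                     seed: int = 0, transpose: bool = False) -> ClusteringResult:
    """Best-of-n_init k-means on the observation matrix; deterministic given seed."""
    mat, obs_ids, _ = _obs_matrix(x, transpose)
    n = mat.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range for n={n} observations")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(mat)
    labels = km.labels_.astype(int)
    return ClusteringResult("kmeans", obs_ids, {k: labels}, {k: float(km.inertia_)})


def pam_partition(x: ExpressionMatrix, k: int, seed: int = 0,
                  transpose: bool = False, max_iter: int = 100) -> ClusteringResult:
    """Partitioning Around Medoids (build + swap) under Euclidean distance."""
    mat, obs_ids, _ = _obs_matrix(x, transpose)
    n = mat.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range for n={n} observations")
    d = squareform(pdist(mat, metric="euclidean"))
    # BUILD: greedy medoid selection
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, -1
        current = d[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - d[:, j], 0).sum()
            if gain > best_gain or (gain == best_gain and j < best_j):
                best_gain, best_j = gain, j
        medoids.append(best_j)
    # SWAP
    for _ in range(max_iter):
        improved = False
        cost = d[:, medoids].min(axis=1).sum()
        for mi in range(k):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = j
                new_cost = d[:, trial].min(axis=1).sum()
                if new_cost < cost - 1e-12:
                    medoids, cost, improved = trial, new_cost, True
        if not improved:
            break
    labels = np.argmin(d[:, medoids], axis=1).astype(int)
    return ClusteringResult("pam", obs_ids, {k: labels}, {k: _wss(mat, labels)})


def elbow_profile(x: ExpressionMatrix, k_range: range = range(2, 8),
                  seed: int = 0, n_init: int = 25,
                  transpose: bool = False) -> tuple[ClusteringResult, int, bool]:
    """WSS-per-k k-means profile with an advisory elbow suggestion.

    Suggested k maximizes the second difference of the WSS curve. Monotone WSS
    is enforced by also seeding each k with the previous solution's centroids
    plus the worst-fit sample. Returns (result, suggested_k, low_confidence).
    """
    ks = sorted(k_range)
    if len(ks) < 3 or ks[0] < 1:
        raise ValidationError("k_range must cover at least three values with k >= 1")
    mat, obs_ids, _ = _obs_matrix(x, transpose)
    if ks[-1] > mat.shape[0]:
        raise ValidationError(f"k_range max {ks[-1]} exceeds n={mat.shape[0]}")
    assignments: dict[int, np.ndarray] = {}
    wss: dict[int, float] = {}
    prev_centers: np.ndarray | None = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(mat)
        best = km
        if prev_centers is not None and prev_centers.shape[0] == k - 1:
            resid = ((mat - prev_centers[
                np.argmin(((mat[:, None, :] - prev_centers[None]) ** 2).sum(-1), axis=1)
            ]) ** 2).sum(axis=1)
            init = np.vstack([prev_centers, mat[int(np.argmax(resid))]])
            km2 = KMeans(n_clusters=k, n_init=1, init=init, random_state=seed).fit(mat)
            if km2.inertia_ < best.inertia_:
                best = km2
        assignments[k] = best.labels_.astype(int)
        wss[k] = float(best.inertia_)
        prev_centers = best.cluster_centers_
    curve = np.array([wss[k] for k in ks])
    second_diff = curve[:-2] - 2 * curve[1:-1] + curve[2:]
    pos = int(np.argmax(second_diff))
    suggested = ks[pos + 1]
    total_drop = max(curve[0] - curve[-1], 1e-12)
    low_confidence = bool(second_diff[pos] / total_drop < 0.2)
    result = ClusteringResult("kmeans", obs_ids, assignments, wss)
    return result, suggested, low_confidence


def clustree_transitions(result: ClusteringResult) -> pd.DataFrame:
    """Counts of shared samples between clusters at consecutive k levels."""
    ks = sorted(result.assignments)
    if len(ks) < 2:
        raise ValidationError("transitions require assignments at >= 2 k levels")
    for a, b in zip(ks[:-1], ks[1:]):
        if b != a + 1:
            raise ValidationError(f"missing k level between {a} and {b}")
    rows = []
    for a, b in zip(ks[:-1], ks[1:]):
        la, lb = result.assignments[a], result.assignments[b]
        for ca in np.unique(la):
            for cb in np.unique(lb):
                count = int(((la == ca) & (lb == cb)).sum())
                if count:
                    rows.append((a, int(ca), b, int(cb), count))
    return pd.DataFrame(rows, columns=["k_from", "cluster_from", "k_to",
                                       "cluster_to", "count"])


def mahalanobis_from_centroid(x: ExpressionMatrix, genes) -> MahalanobisReport:
    """Per-sample Mahalanobis distance from the centroid in a gene subspace.

    d(s) = sqrt((v_s - mu)^T Sigma^-1 (v_s - mu)) with mu and Sigma (n-1
    denominator) estimated from all samples restricted to ``genes``.
    """
    genes = tuple(genes)
    sub = x.subset_genes(genes)
    if sub.n_samples < len(genes) + 1:
        raise ValidationError(
            f"need >= {len(genes) + 1} samples for a {len(genes)}-gene covariance"
        )
    pts = sub.values.T  # samples x genes
    mu = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular covariance for the requested gene subset; consider "
            "regularization (off by default)"
        ) from None
    diff = pts - mu
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return MahalanobisReport(sub.sample_ids, genes, np.sqrt(np.maximum(d2, 0.0)), cov)
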