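import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from txsig.datatypes import ExpressionMatrix, ValidationError
from txsig.unsupervised import (
    clustree_transitions,
    elbow_profile,
    hierarchical_cluster,
    kmeans_partition,
    mahalanobis_from_centroid,
    pam_partition,
    pca_decompose,
)


def matrix_from(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or tuple(f"g{i}" for i in range(values.shape[0]))
    samples = samples or tuple(f"s{j}" for j in range(values.shape[1]))
    return ExpressionMatrix(genes, samples, values, "log2fc")


def naive_average_linkage(points):
    """O(n^3) brute-force average linkage on Euclidean distances.

    Returns merge heights in order, for comparison with the scipy route.
    """
    clusters = {i: [i] for i in range(len(points))}
    d = squareform(pdist(points))
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestPca:
    def test_variance_sums_to_100(self, small_matrix):
        res = pca_decompose(small_matrix)
        assert res.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        for col in res.contributions_pct.T:
            assert col.sum() == pytest.approx(100.0, abs=1e-6)

    def test_rank_one_duplicate_gene(self, rng):
        g1 = rng.normal(size=10)
        x = matrix_from(np.vstack([g1, 2 * g1 + 1]))
        res = pca_decompose(x, scale=True)
        assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_eigen_oracle(self, rng):
        # independent route: eigenvalues of the gene-gene correlation matrix
        x = matrix_from(rng.normal(size=(13, 18)))
        res = pca_decompose(x, scale=True)
        corr = np.corrcoef(x.values)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        expected = 100.0 * eig / eig.sum()
        k = len(res.explained_variance_pct)
        np.testing.assert_allclose(res.explained_variance_pct, expected[:k],
                                   atol=1e-8)

    def test_permutation_invariance(self, small_matrix, rng):
        perm = rng.permutation(small_matrix.n_samples)
        shuffled = matrix_from(small_matrix.values[:, perm],
                               genes=small_matrix.gene_ids)
        np.testing.assert_allclose(
            pca_decompose(small_matrix).explained_variance_pct,
            pca_decompose(shuffled).explained_variance_pct, atol=1e-8)

    def test_zero_variance_gene_with_scale(self):
        x = matrix_from([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValidationError, match="g0"):
            pca_decompose(x, scale=True)


class TestHierarchical:
    def test_identical_samples_merge_first_at_zero(self, rng):
        base = rng.normal(size=4)
        values = np.column_stack([base, base, base + 5.0])
        res = hierarchical_cluster(matrix_from(values), distance="euclidean")
        assert res.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.merges[0, :2].astype(int)) == {0, 1}

    def test_naive_oracle_merge_heights(self, rng):
        values = rng.normal(size=(4, 5))  # 5 samples
        res = hierarchical_cluster(matrix_from(values), distance="euclidean")
        expected = naive_average_linkage(values.T)
        np.testing.assert_allclose(res.merges[:, 2], expected, atol=1e-10)

    def test_cut_at_n_singletons(self, small_matrix):
        res = hierarchical_cluster(small_matrix, distance="euclidean")
        n = small_matrix.n_samples
        assert len(np.unique(res.labels(n))) == n
        for k in range(1, n + 1):
            assert len(np.unique(res.labels(k))) == k

    def test_wss_non_increasing_in_k(self, small_matrix):
        res = hierarchical_cluster(small_matrix, distance="euclidean")
        ks = sorted(res.wss)
        wss = [res.wss[k] for k in ks]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))

    def test_constant_sample_under_pearson_named(self):
        values = np.array([[1.0, 5.0], [1.0, 6.0], [1.0, 7.0]])
        with pytest.raises(ValidationError, match="s0"):
            hierarchical_cluster(matrix_from(values))


class TestKmeansAndElbow:
    def test_k1_equals_total_ss(self, small_matrix):
        res = kmeans_partition(small_matrix, k=1, seed=0)
        pts = small_matrix.values.T
        tss = ((pts - pts.mean(axis=0)) ** 2).sum()
        assert res.wss[1] == pytest.approx(tss)

    def test_kn_zero_wss(self, small_matrix):
        n = small_matrix.n_samples
        res = kmeans_partition(small_matrix, k=n, seed=0)
        assert res.wss[n] == pytest.approx(0.0, abs=1e-9)

    def test_k_out_of_range(self, small_matrix):
        with pytest.raises(ValidationError):
            kmeans_partition(small_matrix, k=small_matrix.n_samples + 1, seed=0)

    def test_blobs_perfect_recovery(self, blob_matrix):
        x, truth = blob_matrix
        res = kmeans_partition(x, k=3, seed=1)
        assert adjusted_rand_score(truth, res.labels(3)) == 1.0

    def test_elbow_on_blobs(self, blob_matrix):
        x, truth = blob_matrix
        result, suggested, low_conf = elbow_profile(x, range(1, 8), seed=2)
        assert suggested == 3
        assert not low_conf
        ks = sorted(result.wss)
        wss = [result.wss[k] for k in ks]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))

    def test_single_blob_low_confidence(self, rng):
        x = matrix_from(rng.normal(size=(5, 40)))
        _, _, low_conf = elbow_profile(x, range(1, 8), seed=3)
        assert low_conf

    def test_determinism(self, blob_matrix):
        x, _ = blob_matrix
        a = kmeans_partition(x, 3, seed=5)
        b = kmeans_partition(x, 3, seed=5)
        np.testing.assert_array_equal(a.labels(3), b.labels(3))

    def test_pam_shares_contract(self, blob_matrix):
        x, truth = blob_matrix
        res = pam_partition(x, k=3)
        assert adjusted_rand_score(truth, res.labels(3)) == 1.0
        assert res.method == "pam"


class TestClustree:
    def test_row_sums_conserved(self, blob_matrix):
        x, _ = blob_matrix
        result, _, _ = elbow_profile(x, range(1, 5), seed=0)
        table = clustree_transitions(result)
        n = x.n_samples
        for k in (1, 2, 3):
            assert table[table["k_from"] == k]["count"].sum() == n

    def test_nested_split_structure(self):
        from txsig.unsupervised import ClusteringResult
        labels1 = np.zeros(6, int)
        labels2 = np.array([0, 0, 0, 1, 1, 1])
        labels3 = np.array([0, 0, 2, 1, 1, 1])
        res = ClusteringResult("kmeans", tuple(f"s{i}" for i in range(6)),
                               {1: labels1, 2: labels2, 3: labels3})
        table = clustree_transitions(res)
        step = table[(table["k_from"] == 2)]
        # block structure: cluster 0 splits into {0,2}, cluster 1 maps to 1
        assert set(map(tuple, step[["cluster_from", "cluster_to", "count"]]
                       .itertuples(index=False))) == {(0, 0, 2), (0, 2, 1), (1, 1, 3)}

    def test_missing_level_rejected(self):
        from txsig.unsupervised import ClusteringResult
        res = ClusteringResult("kmeans", ("a", "b"),
                               {1: np.zeros(2, int), 3: np.zeros(2, int)})
        with pytest.raises(ValidationError, match="missing k level"):
            clustree_transitions(res)


class TestMahalanobis:
    def _matrix(self, pts, genes):
        return matrix_from(np.asarray(pts, float).T, genes=genes)

    def test_sample_at_centroid_zero(self):
        pts = [[0, 0, 0], [2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0],
               [0, 0, 2], [0, 0, -2]]
        x = self._matrix(pts, ("a", "b", "c"))
        rep = mahalanobis_from_centroid(x, ("a", "b", "c"))
        assert rep.distances[0] == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_equals_euclidean(self, rng):
        # whiten a random cloud so its sample covariance is the identity
        raw = rng.normal(size=(30, 3))
        raw -= raw.mean(axis=0)
        cov = np.cov(raw, rowvar=False)
        white = raw @ np.linalg.inv(np.linalg.cholesky(cov)).T
        x = self._matrix(white, ("a", "b", "c"))
        rep = mahalanobis_from_centroid(x, ("a", "b", "c"))
        euclid = np.linalg.norm(white - white.mean(axis=0), axis=1)
        np.testing.assert_allclose(rep.distances, euclid, atol=1e-8)

    def test_hand_2d_diagonal_covariance(self):
        # sample covariance diag(4, 1): a step along the first axis counts half
        xs = np.array([2.0, -2.0, 2.0, -2.0])
        ys = np.array([1.0, 1.0, -1.0, -1.0])
        xs = xs / xs.std(ddof=1) * 2.0
        ys = ys / ys.std(ddof=1) * 1.0
        x = self._matrix(np.column_stack([xs, ys]), ("a", "b"))
        rep = mahalanobis_from_centroid(x, ("a", "b"))
        expected = np.sqrt((xs / 2.0) ** 2 + ys ** 2)
        np.testing.assert_allclose(rep.distances, expected, atol=1e-9)

    def test_singular_covariance_rejected(self):
        pts = [[1, 2, 3], [2, 4, 6], [3, 6, 9], [4, 8, 12], [0, 0, 0]]
        x = self._matrix(pts, ("a", "b", "c"))
        with pytest.raises(ValidationError, match="singular|regulariz"):
            mahalanobis_from_centroid(x, ("a", "b", "c"))
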