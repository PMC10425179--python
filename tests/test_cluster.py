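import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from cortarch.cluster import (Dendrogram, cophenetic_correlation,
                              fingerprint_distance, kmeans_select,
                              linkage_comparison, pca, ward_cluster)


def brute_force_ward(x: np.ndarray):
    """Exhaustive Ward agglomeration oracle: at each step merge the pair of
    clusters with the smallest increase in within-cluster sum of squares."""
    clusters = {i: [i] for i in range(len(x))}
    merges = []

    def ess(members):
        pts = x[members]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    next_id = len(x)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            delta = (ess(clusters[i] + clusters[j]) - ess(clusters[i])
                     - ess(clusters[j]))
            if best is None or delta < best[0] - 1e-12:
                best = (delta, i, j)
        delta, i, j = best
        merges.append((frozenset(clusters[i]) , frozenset(clusters[j]), delta))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


class TestFingerprintDistance:
    def test_identical_zero_and_unit_difference(self):
        a = np.zeros(14)
        assert fingerprint_distance(a, a) == 0.0
        b = a.copy()
        b[3] = 1.0
        assert fingerprint_distance(a, b) == 1.0

    def test_matches_summation_oracle(self, rng):
        a, b = rng.normal(size=14), rng.normal(size=14)
        oracle = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert fingerprint_distance(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fingerprint_distance(np.zeros(14), np.zeros(13))


class TestWard:
    def test_duplicates_merge_first_at_zero(self, rng):
        x = rng.normal(size=(5, 3))
        x[3] = x[1]
        dend = ward_cluster(pd.DataFrame(x, index=list("abcde")))
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {1, 3}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_points_merge_nearest(self):
        x = np.array([[0.0], [1.0], [10.0]])
        dend = ward_cluster(x)
        assert {int(dend.linkage[0, 0]), int(dend.linkage[0, 1])} == {0, 1}

    def test_merge_sequence_matches_exhaustive_oracle(self, rng):
        x = rng.normal(size=(5, 4))
        dend = ward_cluster(x)
        oracle = brute_force_ward(x)
        n = len(x)
        members = {i: frozenset([i]) for i in range(n)}
        for step, (i, j, h, _) in enumerate(dend.linkage):
            got = {members[int(i)], members[int(j)]}
            members[n + step] = members[int(i)] | members[int(j)]
            assert got == {oracle[step][0], oracle[step][1]}
            # scipy ward heights encode sqrt(2 * delta ESS)
            assert h == pytest.approx(np.sqrt(2 * oracle[step][2]), rel=1e-9)

    def test_duplicate_labels_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 2)), index=["a", "a", "b"])
        with pytest.raises(ValueError, match="duplicate"):
            ward_cluster(df)

    def test_heights_monotone(self, density_fixture):
        from cortarch.quant import zscore_table
        means, _ = density_fixture
        dend = ward_cluster(zscore_table(means))
        assert np.all(np.diff(dend.linkage[:, 2]) >= -1e-10)

    def test_row_order_invariance(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 5)),
                         index=[f"a{i}" for i in range(8)])
        perm = rng.permutation(8)
        d1 = ward_cluster(x)
        d2 = ward_cluster(x.iloc[perm])
        # compare label-aligned cophenetic distances
        def coph_by_label(dend, frame):
            c = hierarchy.cophenet(dend.linkage)
            labels = dend.labels
            out = {}
            for (i, j), v in zip(itertools.combinations(range(len(labels)), 2), c):
                out[frozenset((labels[i], labels[j]))] = v
            return out
        m1, m2 = coph_by_label(d1, x), coph_by_label(d2, x)
        assert all(abs(m1[k] - m2[k]) < 1e-9 for k in m1)

    def test_newick_export_roundtrip_leaf_set(self, rng):
        dend = ward_cluster(pd.DataFrame(rng.normal(size=(4, 3)),
                                         index=["w", "x", "y", "z"]))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for leaf in "wxyz":
            assert leaf in nwk


class TestCophenetic:
    def test_perfect_on_ultrametric_data(self):
        # two tight pairs with all four cross distances equal: every triple
        # has its two largest distances equal, i.e. an exact ultrametric
        h = 2.0
        pts = np.array([
            [0.5, 0.0, 0.0], [-0.5, 0.0, 0.0],
            [0.0, 0.5, h], [0.0, -0.5, h],
        ])
        d = pdist(pts)
        assert np.unique(np.round(d, 9)).size == 2  # {1, sqrt(0.5 + h^2)}
        dend = ward_cluster(pts)
        r = cophenetic_correlation(dend, pts)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            cophenetic_correlation(ward_cluster(pts), pts)

    def test_linkage_comparison_reports_all_methods(self, density_fixture):
        from cortarch.quant import zscore_table
        means, _ = density_fixture
        coph = linkage_comparison(zscore_table(means))
        assert set(coph.index) == {"ward", "single", "complete", "average"}
        assert ((coph > -1) & (coph < 1)).all()


class TestKMeansSelect:
    @staticmethod
    def blobs(rng, centers, n_per=10, sd=0.1):
        pts = [c + rng.normal(0, sd, size=(n_per, len(c))) for c in centers]
        return np.vstack(pts)

    def test_three_separated_blobs(self, rng):
        centers = [np.array([0.0, 0.0]), np.array([10.0, 0.0]),
                   np.array([0.0, 10.0])]
        hits = 0
        for seed in range(5):
            x = self.blobs(np.random.default_rng(seed), centers)
            sel = kmeans_select(x, k_range=range(2, 6), n_permutations=50,
                                seed=seed, n_restarts=10)
            hits += sel.k == 3
        assert hits >= 4

    def test_single_blob_unsupported(self):
        misses = 0
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=(30, 4))
            sel = kmeans_select(x, k_range=range(2, 5), n_permutations=50,
                                seed=seed, n_restarts=10)
            misses += sel.k == 1
        assert misses >= 4

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(20, 3))
        a = kmeans_select(x, k_range=range(2, 5), n_permutations=20, seed=9,
                          n_restarts=5)
        b = kmeans_select(x, k_range=range(2, 5), n_permutations=20, seed=9,
                          n_restarts=5)
        assert a.k == b.k
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_k_range_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_select(rng.normal(size=(5, 3)), k_range=range(2, 10),
                          n_permutations=5)


class TestPCA:
    def test_collinear_points_single_component(self, rng):
        direction = rng.normal(size=14)
        x = np.outer(np.linspace(-2, 2, 9), direction)
        _, _, frac = pca(x)
        assert frac[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self, rng):
        _, _, frac = pca(rng.normal(size=(8, 14)))
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigen_solver_oracle(self, rng):
        x = rng.normal(size=(8, 14))
        loadings, scores, frac = pca(x)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = loadings.shape[1]
        for j in range(k):
            dot = abs(np.dot(loadings[:, j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(frac, evals[:k] / evals.sum(), atol=1e-12)

    def test_scores_orthogonal(self, rng):
        _, scores, _ = pca(rng.normal(size=(10, 6)))
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-9

    def test_sign_convention(self, rng):
        loadings, _, _ = pca(rng.normal(size=(9, 5)))
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError, match="rank-0"):
            pca(np.ones((5, 3)))
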