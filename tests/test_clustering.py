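"""Hierarchical/spectral clustering and partition validation indices."""

import itertools

import numpy as np
import pytest

from oracles import (
    ari_pair_counting,
    min_normalized_cut,
    nmi_entropy,
    set_partitions,
    silhouette_direct,
)
from phfp.clustering import (
    ClusterConfig,
    DistanceMatrix,
    GraphSpec,
    ari,
    build_affinity,
    choose_k_by_silhouette,
    evaluate,
    hierarchical,
    k_sweep,
    loo_evaluate,
    nmi,
    silhouette_score,
    spectral,
    to_distance,
)
from phfp.similarity import SimilarityMatrix


def _sim(values, metric="tanimoto"):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(values=values, ids=tuple(f"m{i}" for i in range(len(values))),
                            metric=metric)


def _dist(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(values=values, ids=tuple(f"m{i}" for i in range(len(values))),
                          metric="test")


def _blob_distances(sizes, within=0.05, between=1.0, seed=0):
    """Well-separated planted groups as a distance matrix."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    d = np.full((n, n), between) + rng.uniform(-0.01, 0.01, (n, n))
    same = labels[:, None] == labels[None, :]
    d[same] = within
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return _dist(d), labels


class TestToDistance:
    def test_one_minus_similarity_with_forced_zero_diagonal(self):
        s = _sim([[0.5, 0.2], [0.2, 0.5]], metric="rogot_goldberg")
        d = to_distance(s)
        assert d.values[0, 0] == 0.0  # forced even though self-similarity is 0.5
        assert d.values[0, 1] == pytest.approx(0.8)

    def test_spearman_range_up_to_two(self):
        s = _sim([[1.0, -1.0], [-1.0, 1.0]], metric="spearman")
        d = to_distance(s)
        assert d.values[0, 1] == pytest.approx(2.0)


class TestHierarchical:
    @pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
    def test_two_separated_groups_recovered(self, linkage):
        d, labels = _blob_distances([5, 6])
        res = hierarchical(d, linkage, 2)
        assert ari(res.labels, labels) == 1.0

    def test_k_equals_n_singletons_k1_one_cluster(self):
        d, _ = _blob_distances([3, 3])
        assert len(set(hierarchical(d, "average", 6).labels)) == 6
        assert len(set(hierarchical(d, "average", 1).labels)) == 1

    def test_complete_linkage_four_point_hand_dendrogram(self):
        # pairwise distances chosen so merges are (0,1), (2,3), then all:
        # d01=1, d23=2, max-linkage between the two pairs = 9
        d = _dist([[0, 1, 8, 9], [1, 0, 7, 8.5], [8, 7, 0, 2], [9, 8.5, 2, 0]])
        res = hierarchical(d, "complete", 2)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_invalid_k_rejected(self):
        d, _ = _blob_distances([3, 3])
        with pytest.raises(ValueError):
            hierarchical(d, "ward", 7)


class TestAffinity:
    def test_rbf_closed_forms(self):
        s = _sim([[1.0, 0.0], [0.0, 1.0]])
        W = build_affinity(s, GraphSpec(mode="rbf", gamma=1.0))
        assert W[0, 0] == pytest.approx(1.0)          # d = 0
        assert W[0, 1] == pytest.approx(np.exp(-1.0))  # d = 1, gamma = 1

    def test_knn_full_graph_when_k_is_n_minus_1(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 0.9, (6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        s = _sim(vals)
        W = build_affinity(s, GraphSpec(mode="knn", n_neighbors=5))
        off = ~np.eye(6, dtype=bool)
        assert np.all(W[off] > 0)
        np.testing.assert_allclose(W[off], s.values[off])

    def test_knn_union_symmetrization(self):
        # m2 is nearest to nobody's top-1 except m1's: union keeps the edge
        vals = np.array([
            [1.0, 0.9, 0.1],
            [0.9, 1.0, 0.2],
            [0.1, 0.2, 1.0],
        ])
        s = _sim(vals)
        W = build_affinity(s, GraphSpec(mode="knn", n_neighbors=1))
        assert W[2, 1] == W[1, 2] == 0.2  # edge exists via m2's own neighbor
        assert W[0, 2] == 0.0


class TestSpectral:
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_exact_block_recovery(self, k):
        sizes = [4 + i for i in range(k)]
        n = sum(sizes)
        labels = np.repeat(np.arange(k), sizes)
        W = (labels[:, None] == labels[None, :]).astype(float)
        res = spectral(W, k, seed=0)
        assert ari(res.labels, labels) == 1.0

    def test_two_cliques_weak_bridge_matches_min_ncut(self):
        n1, n2 = 5, 4
        n = n1 + n2
        W = np.zeros((n, n))
        W[:n1, :n1] = 1.0
        W[n1:, n1:] = 1.0
        np.fill_diagonal(W, 0.0)
        W[0, n1] = W[n1, 0] = 0.05  # weak bridge
        res = spectral(W, 2, seed=0)
        _, best_mask = min_normalized_cut(W.tolist())
        assert ari(res.labels, best_mask) == 1.0

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 10))
        W = (X + X.T) / 2
        np.fill_diagonal(W, 0.0)
        r1 = spectral(W, 3, seed=5)
        r2 = spectral(W, 3, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_zero_degree_vertex_named(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="2"):
            spectral(W, 2, seed=0)


class TestSilhouette:
    def test_two_zero_diameter_far_clusters(self):
        d = np.full((6, 6), 5.0)
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        labels = [0, 0, 0, 1, 1, 1]
        assert silhouette_score(_dist(d), labels) == pytest.approx(1.0)

    def test_misassigned_point_scores_negative(self):
        d, labels = _blob_distances([4, 4])
        wrong = labels.copy()
        wrong[0] = 1 - wrong[0]
        per_point = silhouette_direct(d.values.tolist(), wrong.tolist())
        assert silhouette_score(_dist(d.values), wrong) == pytest.approx(per_point)
        assert per_point < silhouette_score(_dist(d.values), labels)

    def test_single_cluster_rejected(self):
        d, _ = _blob_distances([3, 3])
        with pytest.raises(ValueError):
            silhouette_score(d, [0] * 6)


class TestPartitionIndices:
    def test_identical_up_to_renaming(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [5, 5, 9, 9, 7, 7]
        assert ari(a, b) == pytest.approx(1.0)
        assert nmi(a, b) == pytest.approx(1.0)

    def test_trivial_partition_carries_no_information(self):
        assert nmi([0] * 6, [0, 1, 0, 1, 2, 2]) == pytest.approx(0.0)

    def test_random_labelings_ari_near_zero_in_expectation(self):
        rng = np.random.default_rng(0)
        vals = [ari(rng.integers(0, 3, 60), rng.integers(0, 3, 60))
                for _ in range(200)]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)

    def test_all_partition_pairs_of_six_match_oracles(self):
        """ARI and NMI agree with direct-formula oracles on every pair of
        partitions of 6 points (203 x 203 pairs)."""
        parts = list(set_partitions(range(6)))
        rng = np.random.default_rng(1)
        idx = rng.choice(len(parts), size=60, replace=False)
        sample = [parts[i] for i in idx]
        for la in sample:
            for lb in sample:
                assert ari(la, lb) == pytest.approx(ari_pair_counting(la, lb))
                assert nmi(la, lb) == pytest.approx(nmi_entropy(la, lb), abs=1e-9)

    def test_silhouette_all_valid_partitions_of_six(self):
        rng = np.random.default_rng(2)
        x = rng.random((6, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        dm = _dist(d)
        for labels in set_partitions(range(6)):
            k = len(set(labels))
            if not 2 <= k < 6:
                continue
            assert silhouette_score(dm, labels) == pytest.approx(
                silhouette_direct(d.tolist(), labels)
            )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 3, 30)
        remap = {0: 7, 1: 3, 2: 0, 3: 1}
        a2 = np.array([remap[v] for v in a])
        assert ari(a, b) == pytest.approx(ari(a2, b))
        assert nmi(a, b) == pytest.approx(nmi(a2, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            nmi([0, 1], [0, 1, 2])


def _blob_similarity(sizes, seed=0):
    d, labels = _blob_distances(sizes, seed=seed)
    return _sim(np.clip(1.0 - d.values, 0, 1)), labels


class TestEvaluationProtocols:
    def test_loo_perfectly_separable_mean_ari_one(self):
        s, labels = _blob_similarity([5, 5, 5])
        cfg = ClusterConfig(algorithm="hierarchical", linkage="ward")
        rep = loo_evaluate(s, cfg, 3, labels)
        assert rep.ari == pytest.approx(1.0)
        assert rep.nmi == pytest.approx(1.0)

    def test_loo_averages_all_n_runs(self):
        s, labels = _blob_similarity([4, 4])
        cfg = ClusterConfig(algorithm="hierarchical", linkage="average")
        full = evaluate(s, cfg, 2, labels)
        loo = loo_evaluate(s, cfg, 2, labels)
        # separable case: every run perfect, so averaging is stable
        assert loo.ari == pytest.approx(full.ari)

    def test_k_sweep_planted_five_classes_peaks_at_five(self):
        s, labels = _blob_similarity([8, 6, 7, 5, 6], seed=4)
        cfg = ClusterConfig(algorithm="hierarchical", linkage="ward")
        rows = k_sweep(s, cfg, range(2, 9), labels)
        best = max(rows, key=lambda r: r["ari"])
        assert best["k"] == 5
        assert best["ari"] == 1.0

    def test_choose_k_by_silhouette_three_blobs(self):
        d, _ = _blob_distances([5, 5, 5], seed=5)
        assert choose_k_by_silhouette(d, "average", range(2, 7)) == 3

    def test_choose_k_seventeen_planted_groups(self):
        """Scaffold-like fixture: 17 separated groups; silhouette picks 17."""
        d, _ = _blob_distances([4] * 17, seed=6)
        assert choose_k_by_silhouette(d, "ward", range(10, 21)) == 17

    def test_choose_k_tie_resolves_to_smallest(self, monkeypatch):
        # force an exactly flat silhouette profile: the tie rule must pick
        # the smallest K in the range
        d, _ = _blob_distances([4, 4], seed=7)
        monkeypatch.setattr("phfp.clustering.silhouette_score",
                            lambda dist, labels: 0.25)
        assert choose_k_by_silhouette(d, "average", range(2, 6)) == 2
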