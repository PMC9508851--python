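import math

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from spotatlas import (
    AffinityModel,
    agglomerate,
    build_spatial_knn,
    conditional_affinities,
    partition_cross_entropy,
    pca_embed,
)

from conftest import truth_labels_for


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPcaEmbed:
    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(0)
        direction = rng.random(6)
        X = np.outer(rng.random(20), direction)
        emb = pca_embed(X, 1)
        assert emb.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_total_variance_conserved_at_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.random((15, 6))
        emb = pca_embed(X, 6)
        Xc = X - X.mean(axis=0)
        total = (Xc**2).sum() / 14
        score_var = (emb.scores**2).sum() / 14
        assert score_var == pytest.approx(total, rel=1e-12)
        assert emb.variance_fraction.sum() == pytest.approx(1.0, rel=1e-12)

    def test_matches_full_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 10))
        emb = pca_embed(X, 5)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        expected = U[:, :5] * s[:5]
        for c in range(5):
            diff = min(np.abs(emb.scores[:, c] - expected[:, c]).max(),
                       np.abs(emb.scores[:, c] + expected[:, c]).max())
            assert diff < 1e-8

    def test_sign_convention_fixes_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        X = rng.random((25, 8))
        emb = pca_embed(X, 4)
        for c in range(4):
            assert emb.loadings[c, np.abs(emb.loadings[c]).argmax()] > 0

    def test_components_truncated_to_rank(self):
        rng = np.random.default_rng(4)
        X = np.tile(rng.random((10, 1)), (1, 7))  # rank 1
        emb = pca_embed(X, 5)
        assert emb.n_components == 1

    def test_variances_non_increasing(self):
        rng = np.random.default_rng(5)
        emb = pca_embed(rng.random((40, 12)), 12)
        assert np.all(np.diff(emb.variance_fraction) <= 1e-12)


# ---------------------------------------------------------------------------
# conditional affinities
# ---------------------------------------------------------------------------

class TestConditionalAffinities:
    def test_equidistant_candidates_give_uniform_row(self):
        # 35 candidates on a circle around bead 0 -> p = 1/35, perplexity 35
        theta = np.linspace(0, 2 * np.pi, 36)[:-1]
        Y = np.vstack([[0.0, 0.0], np.c_[np.cos(theta), np.sin(theta)]])
        aff = conditional_affinities(Y, 35.0, n_candidates=35)
        row = aff.P[0].toarray().ravel()
        np.testing.assert_allclose(row[1:], 1 / 35, atol=1e-9)
        assert aff.realized_perplexity[0] == pytest.approx(35.0, abs=1e-6)

    def test_low_perplexity_concentrates_on_nearest(self):
        Y = np.array([[0.0, 0.0], [1e-4, 0.0], [1.0, 0.0]])
        aff = conditional_affinities(Y, 1.05, n_candidates=2)
        assert aff.P[0, 1] > 0.95

    def test_bisection_hits_target_perplexity(self):
        rng = np.random.default_rng(0)
        Y = rng.random((10, 3))
        aff = conditional_affinities(Y, 5.0, n_candidates=9)
        assert aff.converged.all()
        assert np.abs(aff.realized_perplexity - 5.0).max() < 1e-3
        # self-check against direct entropy evaluation of the stored rows
        for i in range(10):
            p = aff.P[i].toarray().ravel()
            p = p[p > 0]
            assert 2 ** (-(p * np.log2(p)).sum()) == pytest.approx(5.0, abs=2e-3)

    def test_rows_sum_to_one_and_diagonal_zero(self):
        rng = np.random.default_rng(1)
        aff = conditional_affinities(rng.random((50, 5)), 10.0)
        aff.check()
        rows = np.asarray(aff.P.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 1.0, atol=1e-9)
        assert np.abs(aff.P.diagonal()).max() == 0.0

    def test_candidate_count_capped_by_n(self):
        rng = np.random.default_rng(2)
        aff = conditional_affinities(rng.random((12, 2)), 35.0)
        assert aff.m == 11
        assert np.abs(aff.realized_perplexity - 11.0).max() < 1e-3


# ---------------------------------------------------------------------------
# partition cross-entropy
# ---------------------------------------------------------------------------

def uniform_affinity(n):
    P = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(P, 0.0)
    return sp.csr_matrix(P)


class TestPartitionCrossEntropy:
    def test_single_cluster_uniform_p_gives_log_n_minus_1(self):
        n = 8
        H = partition_cross_entropy(uniform_affinity(n), np.zeros(n, int))
        assert H == pytest.approx(math.log(n - 1), rel=1e-12)

    def test_three_bead_hand_oracle(self):
        # P: p(1|0)=1, p(0|1)=1, p(0|2)=1; partition {0,1},{2}; eps = 1e-6
        eps = 1e-6
        n = 3
        P = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [1, 0, 0]], dtype=float))
        labels = np.array([0, 0, 1])
        # rows 0 and 1: cluster size 2, delta = eps*(n-2), q_in = (1-delta)/1
        # row 2: singleton, all mass on the floor q = eps
        delta = eps * (n - 2)
        expected = (-math.log(1 - delta) - math.log(1 - delta) - math.log(eps)) / n
        assert partition_cross_entropy(P, labels, eps) == pytest.approx(expected, rel=1e-12)

    def test_isolating_a_self_contained_bead_increases_h(self):
        # bead 3's whole P-mass is inside cluster {2,3}; moving it to a
        # singleton pushes that mass onto the floor
        P = np.zeros((4, 4))
        P[0, 1] = P[1, 0] = 1.0
        P[2, 3] = P[3, 2] = 1.0
        P = sp.csr_matrix(P)
        together = partition_cross_entropy(P, np.array([0, 0, 1, 1]))
        isolated = partition_cross_entropy(P, np.array([0, 0, 1, 2]))
        assert isolated > together

    def test_epsilon_too_large_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            partition_cross_entropy(uniform_affinity(5), np.zeros(5, int), epsilon=0.5)


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

def spec_cross_entropy(P_dense, clusters, epsilon):
    """From-scratch cross-entropy by the stated Q construction (oracle)."""
    n = P_dense.shape[0]
    label_of = {}
    for cid, members in clusters.items():
        for i in members:
            label_of[i] = cid
    H = 0.0
    for i in range(n):
        s = len(clusters[label_of[i]])
        delta = epsilon * (n - s)
        for j in range(n):
            p = P_dense[i, j]
            if p == 0 or i == j:
                continue
            if label_of[j] == label_of[i] and s >= 2:
                q = (1 - delta) / (s - 1)
            else:
                q = epsilon
            H -= p * math.log(q)
    return H / n


def oracle_greedy(P_dense, bead_adj, target_k, epsilon):
    """Exhaustive argmin search over adjacent-pair merges at every step."""
    n = P_dense.shape[0]
    clusters = {i: {i} for i in range(n)}
    merges = []
    while len(clusters) > target_k:
        H0 = spec_cross_entropy(P_dense, clusters, epsilon)
        best = None
        ids = sorted(clusters)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                adjacent = any(bead_adj[i, j] for i in clusters[a] for j in clusters[b])
                if not adjacent:
                    continue
                trial = {k: v for k, v in clusters.items() if k not in (a, b)}
                trial[a] = clusters[a] | clusters[b]
                dH = spec_cross_entropy(P_dense, trial, epsilon) - H0
                key = (dH, a, b)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        dH, a, b = best
        clusters[a] = clusters[a] | clusters.pop(b)
        merges.append((a, b, dH))
    return merges


def make_affinity(P_csr):
    n = P_csr.shape[0]
    return AffinityModel(P=P_csr, sigma=np.ones(n), perplexity=2.0, m=n - 1,
                         realized_perplexity=np.full(n, 2.0),
                         converged=np.ones(n, dtype=bool))


def random_instance(rng, n):
    xy = rng.random((n, 2)) * 10
    graph = build_spatial_knn(xy, 2)
    P = rng.random((n, n))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return xy, graph, sp.csr_matrix(P)


class TestAgglomerate:
    def test_target_n_returns_singletons(self):
        rng = np.random.default_rng(0)
        xy, graph, P = random_instance(rng, 6)
        part = agglomerate(make_affinity(P), graph, 6, positions=xy)
        assert part.n_clusters == 6
        assert part.merge_log == []

    def test_block_structured_pairs_merge_first(self):
        # path graph 0-1-2-3; P pairs (0,1) and (2,3) -> first merges join them
        xy = np.c_[np.arange(4.0), np.zeros(4)]
        graph = build_spatial_knn(xy, 1)
        P = np.zeros((4, 4))
        P[0, 1] = P[1, 0] = P[2, 3] = P[3, 2] = 1.0
        part = agglomerate(make_affinity(sp.csr_matrix(P)), graph, 2, positions=xy)
        first_two = {(r.left, r.right) for r in part.merge_log[:2]}
        assert first_two == {(0, 1), (2, 3)}

    def test_greedy_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            n = int(rng.integers(4, 9))
            xy, graph, P = random_instance(rng, n)
            if graph.n_components() != 1:
                continue
            checked += 1
            part = agglomerate(make_affinity(P), graph, 1, positions=xy)
            expected = oracle_greedy(P.toarray(), graph.adjacency().toarray(), 1, 1e-12)
            got = [(r.left, r.right, r.delta_h) for r in part.merge_log]
            assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
            for (_, _, dh_got), (_, _, dh_exp) in zip(got, expected):
                assert dh_got == pytest.approx(dh_exp, abs=1e-9)

    def test_merge_count_and_incremental_h_agree_with_direct(self):
        rng = np.random.default_rng(3)
        xy, graph, P = random_instance(rng, 30)
        part = agglomerate(make_affinity(P), graph, 5, positions=xy)
        assert len(part.merge_log) == 30 - part.n_clusters
        direct = partition_cross_entropy(P, part.labels - 1)
        assert part.cross_entropy == pytest.approx(direct, rel=1e-9)

    def test_labels_are_contiguous_and_size_ordered(self):
        rng = np.random.default_rng(4)
        xy, graph, P = random_instance(rng, 40)
        part = agglomerate(make_affinity(P), graph, 6, positions=xy)
        sizes = [len(part.members[k]) for k in sorted(part.members)]
        assert sorted(part.members) == list(range(1, part.n_clusters + 1))
        assert sizes == sorted(sizes, reverse=True)
        assert sum(sizes) == 40

    def test_clusters_are_spatially_connected(self, bench_normalized):
        M, _ = bench_normalized
        graph = build_spatial_knn(M.xy, 20)
        emb = pca_embed(M.layer("normalized"), 20)
        part = agglomerate(conditional_affinities(emb, 35.0), graph, 10,
                           positions=M.xy)
        assert part.bridged_steps == 0
        A = graph.adjacency()
        for members in part.members.values():
            sub = A[np.ix_(members, members)]
            ncomp = sp.csgraph.connected_components(sub, directed=False)[0]
            assert ncomp == 1

    def test_disconnected_graph_without_bridging_stops_at_components(self):
        # two far-apart strips; k=1 keeps them disconnected
        xy = np.r_[np.c_[np.arange(5.0), np.zeros(5)],
                   np.c_[np.arange(5.0) + 1000, np.zeros(5)]]
        graph = build_spatial_knn(xy, 1)
        assert graph.n_components() == 2
        rng = np.random.default_rng(0)
        P = rng.random((10, 10))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        part = agglomerate(make_affinity(sp.csr_matrix(P)), graph, 1,
                           positions=xy, bridge=False)
        assert part.n_clusters == 2
        bridged = agglomerate(make_affinity(sp.csr_matrix(P)), graph, 1,
                              positions=xy, bridge=True)
        assert bridged.n_clusters == 1
        assert bridged.bridged_steps == 1
        assert any(r.bridged for r in bridged.merge_log)

    def test_domain_recovery_single_seed(self, bench_normalized):
        M, truth = bench_normalized
        graph = build_spatial_knn(M.xy, 20)
        emb = pca_embed(M.layer("normalized"), 20)
        part = agglomerate(conditional_affinities(emb, 35.0), graph, 4,
                           positions=M.xy)
        ari = adjusted_rand_score(truth_labels_for(M, truth), part.labels)
        assert ari >= 0.9

    def test_invalid_target_rejected(self):
        rng = np.random.default_rng(5)
        xy, graph, P = random_instance(rng, 5)
        with pytest.raises(ValueError, match="target_k"):
            agglomerate(make_affinity(P), graph, 6)
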