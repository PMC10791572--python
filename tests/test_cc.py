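"""Cluster constructor: graph, seeds, propagation, merging, expansion."""

import numpy as np
import pytest

from conftest import make_cell_graph, random_cell_graph
from scqa.cc import (
    ClusterState,
    build_cell_graph,
    expand_clusters,
    generate_seeds,
    group_cells,
    internal_edges,
    k_out_for,
    node_cluster_similarity,
    node_densities,
    node_unlabeled_similarity,
    pearson_rows,
    propagate_labels,
    propagate_to_convergence,
    prune_and_merge,
    run_scqa,
)
from scqa.lc1 import LandmarkMatrix
from scqa.metrics import ari
from scqa.preprocess import ExpressionMatrix, ScqaParams


def _lm(values) -> LandmarkMatrix:
    values = np.asarray(values, dtype=float)
    return LandmarkMatrix(
        cell_ids=[f"c{j}" for j in range(values.shape[0])],
        landmark_ids=[f"LM_{r}" for r in range(values.shape[1])],
        values=values,
    )


def _state(G, clusters: dict[int, list[int]], densities=None) -> ClusterState:
    labels = np.full(G.n, -1, dtype=np.int64)
    for lbl, members in clusters.items():
        labels[members] = lbl
    if densities is None:
        densities = node_densities(G)
    order = np.lexsort((np.arange(G.n), -densities))
    state = ClusterState(
        labels=labels, densities=densities, beta=0.0, order=order,
        clusters={l: sorted(m) for l, m in clusters.items()},
        next_label=max(clusters, default=-1) + 1,
    )
    return state


class TestGraphConstruction:
    @pytest.mark.parametrize("n,k", [(500, 50), (9999, 999), (10000, 500), (20000, 1000), (5, 1)])
    def test_out_degree_rule(self, n, k):
        assert k_out_for(n) == k

    def test_duplicate_cells_are_top_neighbors(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (30, 4))
        values[7] = values[3]  # exact duplicate rows
        G = build_cell_graph(_lm(values))
        assert G.k_out == 3
        assert 7 in G.out[3] and 3 in G.out[7]
        assert G.weights[3, 7] == pytest.approx(1.0)

    def test_constant_row_has_zero_similarity(self):
        values = np.vstack([np.full(3, 0.5), np.eye(3)])
        W = pearson_rows(values)
        np.testing.assert_allclose(W[0], 0.0)

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ValueError, match="2 landmarks"):
            build_cell_graph(_lm(np.ones((5, 1))))


class TestGroupCells:
    def test_equality_partition(self):
        groups = group_cells(_lm([[1, 0], [1, 0], [0, 1]]))
        assert groups == [[0, 1], [2]]

    def test_all_identical_rows_one_group(self):
        assert group_cells(_lm(np.ones((4, 2)))) == [[0, 1, 2, 3]]

    def test_all_distinct_rows_singletons(self):
        groups = group_cells(_lm(np.eye(4)))
        assert groups == [[0], [1], [2], [3]]


class TestDensities:
    def test_mean_of_out_edges(self):
        W = np.zeros((3, 3))
        W[0, 1], W[0, 2] = 0.8, 0.6
        G = make_cell_graph([[1, 2], [0, 2], [0, 1]], W)
        assert node_densities(G)[0] == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        G = random_cell_graph(rng, 15, 4)
        dens = node_densities(G)
        for i in range(G.n):
            expected = np.mean([G.weights[i, j] for j in G.out[i]])
            assert dens[i] == pytest.approx(expected)


class TestGenerateSeeds:
    def test_beta_is_min_of_group_maxima(self):
        rng = np.random.default_rng(1)
        G = random_cell_graph(rng, 9, 2)
        densities = np.array([0.9, 0.5, 0.1, 0.7, 0.2, 0.1, 0.8, 0.3, 0.1])
        groups = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
        state = generate_seeds(G, groups, densities)
        assert state.beta == pytest.approx(0.7)
        seeded = sorted(i for m in state.clusters.values() for i in m)
        assert seeded == [0, 3, 6, 8][: len(seeded)] or set(seeded) == {0, 3, 6, 8}

    def test_mutual_neighbors_merge_transitively(self):
        # a <-> b, b <-> c mutual chains collapse into one seed {a, b, c}
        out = [[1, 3], [0, 2], [1, 3], [4, 5], [3, 5], [3, 4]]
        W = np.full((6, 6), 0.1)
        G = make_cell_graph(out, W)
        densities = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        state = generate_seeds(G, [[0, 1, 2, 3, 4, 5]], densities)
        assert state.beta == pytest.approx(1.0)
        assert [sorted(m) for m in state.clusters.values()] == [[0, 1, 2]]

    def test_non_mutual_candidates_stay_separate(self):
        # 0 -> 1 but 1 -/-> 0: two separate seeds
        out = [[1, 2], [2, 3], [0, 1], [0, 1]]
        G = make_cell_graph(out, np.full((4, 4), 0.1))
        densities = np.array([1.0, 1.0, 0.0, 0.0])
        state = generate_seeds(G, [[0, 1, 2, 3]], densities)
        assert [sorted(m) for m in state.clusters.values()] == [[0], [1]]


def eq10_oracle(ni, members, state, G, alpha):
    """Literal enumeration of all directed paths of length <= 2."""
    C = set(members)
    U = {j for j in range(G.n) if state.labels[j] < 0} - {ni}
    ON = {i: set(int(v) for v in G.out[i]) for i in range(G.n)}
    IN = {i: {j for j in range(G.n) if i in ON[j]} for i in range(G.n)}
    num = sum(G.weights[ni, r] for r in ON[ni] & C)
    den = len(ON[ni] & C)
    for r in ON[ni] & U:
        num += sum(G.weights[r, p] for p in ON[r] & C)
        den += len(ON[r] & C)
    out_term = num / den if den else 0.0
    num = sum(G.weights[r, ni] for r in IN[ni] & C)
    den = len(IN[ni] & C)
    for r in IN[ni] & U:
        num += sum(G.weights[p, r] for p in IN[r] & C)
        den += len(IN[r] & C)
    in_term = num / den if den else 0.0
    return alpha * out_term + (1 - alpha) * in_term


class TestNodeClusterSimilarity:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_path_enumeration_oracle(self, seed, alpha):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        G = random_cell_graph(rng, n, 3)
        labels = rng.integers(-1, 3, n)
        clusters = {lbl: list(np.where(labels == lbl)[0]) for lbl in (0, 1, 2)}
        clusters = {l: m for l, m in clusters.items() if m}
        state = _state(G, clusters)
        state.labels = labels.astype(np.int64)
        for ni in np.where(labels < 0)[0]:
            for lbl in clusters:
                got = node_cluster_similarity(int(ni), lbl, state, G, alpha)
                want = eq10_oracle(int(ni), clusters[lbl], state, G, alpha)
                assert got == pytest.approx(want), (ni, lbl)

    def test_no_paths_gives_zero(self):
        out = [[1], [0], [3], [2]]
        G = make_cell_graph(out, np.full((4, 4), 0.9))
        state = _state(G, {0: [2, 3]})
        assert node_cluster_similarity(0, 0, state, G, 0.5) == 0.0

    def test_symmetric_graph_convexity(self):
        # both directions see the same single edge weight s = 0.4
        out = [[1], [0], [0]]
        W = np.full((3, 3), 0.4)
        G = make_cell_graph(out, W)
        state = _state(G, {0: [1]})
        state.labels[2] = 9  # keep node 2 out of U
        for alpha in (0.0, 0.3, 1.0):
            assert node_cluster_similarity(0, 0, state, G, alpha) == pytest.approx(0.4)


class TestNodeUnlabeledSimilarity:
    def test_hand_computed_mixture(self):
        # ON0 ∩ U weights [0.4, 0.6]; IN0 ∩ U weights [0.2]
        W = np.zeros((4, 4))
        W[0, 1], W[0, 2] = 0.4, 0.6
        W[3, 0] = 0.2
        out = [[1, 2], [2, 3], [1, 3], [0, 1]]
        G = make_cell_graph(out, W)
        state = _state(G, {})
        assert node_unlabeled_similarity(0, state, G, 0.5) == pytest.approx(0.35)
        assert node_unlabeled_similarity(0, state, G, 1.0) == pytest.approx(0.5)

    def test_alone_in_unlabeled_set_is_zero(self):
        out = [[1], [0], [0]]
        G = make_cell_graph(out, np.full((3, 3), 0.9))
        state = _state(G, {0: [1, 2]})
        assert node_unlabeled_similarity(0, state, G, 0.5) == 0.0


class TestPropagation:
    def test_node_next_to_single_cluster_is_absorbed(self):
        out = [[1, 2], [0, 2], [0, 1]]
        G = make_cell_graph(out, np.full((3, 3), 0.8))
        state = _state(G, {0: [1, 2]})
        propagate_labels(state, G, 0.5)
        assert state.labels[0] == 0

    def test_exact_tie_with_unlabeled_stays_unlabeled(self):
        # node 0: cluster edge weight equals unlabeled edge weight
        W = np.full((4, 4), 0.5)
        out = [[1, 3], [0, 3], [0, 1], [0, 1]]
        G = make_cell_graph(out, W)
        state = _state(G, {0: [1]})
        before = state.labels.copy()
        propagate_labels(state, G, 0.5)
        assert state.labels[0] == before[0] == -1

    def test_convergence_strictly_shrinks_unlabeled(self, preprocessed):
        from scqa.lc1 import build_qualitative_landmarks
        from scqa.lc2 import build_quantitative_landmarks

        Q1, _ = build_qualitative_landmarks(preprocessed)
        Q2, _ = build_quantitative_landmarks(preprocessed)
        G = build_cell_graph(Q2)
        state = generate_seeds(G, group_cells(Q1), node_densities(G))
        n0 = len(state.unlabeled)
        propagate_to_convergence(state, G, 0.5)
        n1 = len(state.unlabeled)
        assert n1 < n0
        propagate_labels(state, G, 0.5)  # converged: another sweep is a no-op
        assert len(state.unlabeled) == n1


class TestPruneAndMerge:
    def _two_cluster_graph(self, out_edges_small_to_big: int):
        """Small cluster {0,1,2} with 2 internal edges; a larger cluster 3-7."""
        n, k = 8, 2
        out = []
        for i in range(3):
            nbrs = [(i + 1) % 3, (i + 2) % 3]
            out.append(nbrs)
        for i in range(3, 8):
            out.append([3 + (i - 2) % 5, 3 + (i - 1) % 5])
        # redirect edges from the small cluster into the big one
        count = 0
        for i in range(3):
            for slot in range(k):
                if count < out_edges_small_to_big:
                    out[i][slot] = 3 + count % 5
                    count += 1
        return make_cell_graph(out, np.full((n, n), 0.5))

    def test_more_external_than_internal_edges_merges(self):
        G = self._two_cluster_graph(4)  # internal 2, external 4
        state = _state(G, {0: [0, 1, 2], 1: [3, 4, 5, 6, 7]})
        assert internal_edges([0, 1, 2], G) == 2
        prune_and_merge(state, G, min_cluster_size=2)
        assert sorted(state.clusters) == [1]
        assert sorted(state.clusters[1]) == list(range(8))
        assert 1 in state.assimilators

    def test_equal_counts_do_not_merge(self):
        G = self._two_cluster_graph(3)  # internal 3, external 3
        state = _state(G, {0: [0, 1, 2], 1: [3, 4, 5, 6, 7]})
        internal = internal_edges([0, 1, 2], G)
        external = sum(int(j >= 3) for i in range(3) for j in G.out[i])
        assert internal == external == 3
        prune_and_merge(state, G, min_cluster_size=2)
        assert sorted(state.clusters) == [0, 1]

    def test_undersized_clusters_dissolved(self):
        G = self._two_cluster_graph(0)
        state = _state(G, {0: [0, 1, 2], 1: [3, 4, 5, 6, 7]})
        prune_and_merge(state, G, min_cluster_size=4)
        assert sorted(state.clusters) == [1]
        np.testing.assert_array_equal(sorted(state.unlabeled), [0, 1, 2])

    def test_assimilators_are_never_merged_away(self):
        # chain: tiny 0 merges into mid 1; mid 1 (now assimilator) would
        # otherwise merge into big 2 but is protected
        n, k = 12, 2
        out = [[1, 2]] * 0
        out = []
        out.append([4, 5])      # 0: leaks into cluster 1's members
        out.append([0, 4])      # 1
        # cluster 1 members 4..6 mostly point into cluster 2 (7..11)
        out.append([3, 7])      # 2 (also small cluster with 0? no)
        out.append([2, 8])      # 3
        out.append([7, 8])      # 4
        out.append([9, 10])     # 5
        out.append([10, 11])    # 6
        for i in range(7, 12):
            out.append([7 + (i - 6) % 5, 7 + (i - 5) % 5])
        G = make_cell_graph(out, np.full((n, n), 0.5))
        state = _state(G, {0: [0, 1], 1: [4, 5, 6], 2: [7, 8, 9, 10, 11]})
        # cluster 0: internal edges 1 (1->0), edges into cluster 1: 3 -> merges
        # cluster 1 (after assimilating) sends 6 edges into cluster 2 with
        # internal edges 1 but must remain separate
        state2 = prune_and_merge(state, G, min_cluster_size=2)
        assert 1 in state2.assimilators
        assert sorted(state2.clusters) == [1, 2]


class TestExpansion:
    def test_every_cell_labeled_afterwards(self, preprocessed):
        from scqa.lc1 import build_qualitative_landmarks
        from scqa.lc2 import build_quantitative_landmarks

        Q1, _ = build_qualitative_landmarks(preprocessed)
        Q2, _ = build_quantitative_landmarks(preprocessed)
        G = build_cell_graph(Q2)
        state = generate_seeds(G, group_cells(Q1), node_densities(G))
        propagate_to_convergence(state, G, 0.5)
        prune_and_merge(state, G, 5)
        expand_clusters(state, G)
        assert len(state.unlabeled) == 0
        sizes = sum(len(m) for m in state.clusters.values())
        assert sizes == G.n

    def test_outlier_founds_new_cluster(self):
        # node 0 has no out-edges into the cluster while its peers average
        # more than zero -> all differences negative -> new cluster
        out = [[1, 2], [2, 3], [1, 3], [4, 5], [3, 5], [3, 4]]
        G = make_cell_graph(out, np.full((6, 6), 0.5))
        state = _state(G, {0: [3, 4, 5]})
        expand_clusters(state, G)
        assert state.labels[0] not in (-1, 0)


class TestRunScqa:
    def test_duplicate_cells_get_identical_labels(self, default_synth):
        E, _ = default_synth
        dup = ExpressionMatrix(
            gene_ids=list(E.gene_ids),
            cell_ids=list(E.cell_ids[:-1]) + ["dup_of_0"],
            values=np.hstack([E.values[:, :-1], E.values[:, [0]]]),
        )
        res = run_scqa(dup, ScqaParams())
        assert res.labels[-1] == res.labels[0]

    def test_pipeline_deterministic(self, default_synth):
        E, _ = default_synth
        a = run_scqa(E, ScqaParams())
        b = run_scqa(E, ScqaParams())
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_contiguous_from_zero(self, default_synth):
        E, _ = default_synth
        res = run_scqa(E, ScqaParams())
        np.testing.assert_array_equal(
            np.unique(res.labels), np.arange(res.n_clusters)
        )

    def test_ablation_modes_run_without_other_matrix(self, default_synth):
        E, truth = default_synth
        res1 = run_scqa(E, ScqaParams(), mode="lc1_only")
        assert res1.Q2 is None and res1.Q1 is not None
        res2 = run_scqa(E, ScqaParams(), mode="lc2_only")
        assert res2.Q1 is None and res2.Q2 is not None
        assert ari(res2.labels, truth) > 0.5

    def test_planted_types_recovered(self, default_synth):
        E, truth = default_synth
        res = run_scqa(E, ScqaParams())
        assert ari(res.labels, truth) >= 0.9
        assert 4 <= res.n_clusters <= 7

    def test_unknown_mode_rejected(self, default_synth):
        E, _ = default_synth
        with pytest.raises(ValueError, match="unknown mode"):
            run_scqa(E, ScqaParams(), mode="nope")

    def test_cluster_landmark_association(self, default_synth):
        E, _ = default_synth
        res = run_scqa(E, ScqaParams())
        assoc = res.cluster_landmarks()
        assert set(assoc) == set(np.unique(res.labels))
        for lm in assoc.values():
            assert 0 <= lm < res.Q2.n_landmarks
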