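"""Tree construction: overlaps, in-proportion, filtering, core edges."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustertree.core import (
    ClusteringSet,
    build_tree,
    compute_overlaps,
    core_edges,
    in_proportion,
)
from clustertree.errors import ClusterTreeError, InvariantError

from conftest import random_clustering_set


def brute_force_overlaps(labels_a, labels_b):
    """Independent oracle: per-sample double loop."""
    table: dict[tuple[str, str], int] = {}
    for la, lb in zip(labels_a, labels_b):
        table[(str(la), str(lb))] = table.get((str(la), str(lb)), 0) + 1
    return table


def make_set(columns: dict[float, list[str]]) -> ClusteringSet:
    res = sorted(columns)
    n = len(next(iter(columns.values())))
    return ClusteringSet(
        sample_ids=tuple(str(i) for i in range(n)),
        resolutions=tuple(res),
        assignments=np.array([columns[r] for r in res], dtype=object).T,
    )


class TestComputeOverlaps:
    def test_identity_clustering_is_diagonal(self):
        table = compute_overlaps(["x", "x", "y", "y"], ["x", "x", "y", "y"])
        assert table.at["x", "x"] == 2 and table.at["y", "y"] == 2
        assert table.at["x", "y"] == 0 and table.at["y", "x"] == 0

    def test_crossed_partition_all_cells_one(self):
        table = compute_overlaps([1, 1, 2, 2], ["a", "b", "a", "b"])
        assert (table.to_numpy() == 1).all()

    def test_marginals_are_cluster_sizes(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 50).astype(str)
        b = rng.integers(0, 4, 50).astype(str)
        table = compute_overlaps(a, b)
        assert table.to_numpy().sum() == 50
        for lab in set(a):
            assert table.loc[lab].sum() == (a == lab).sum()
        for lab in set(b):
            assert table[lab].sum() == (b == lab).sum()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        a = rng.integers(0, int(rng.integers(1, 6)), n).astype(str)
        b = rng.integers(0, int(rng.integers(1, 6)), n).astype(str)
        table = compute_overlaps(a, b)
        oracle = brute_force_overlaps(a, b)
        for i in table.index:
            for j in table.columns:
                assert table.at[i, j] == oracle.get((i, j), 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClusterTreeError, match="equal length"):
            compute_overlaps(["a"], ["a", "b"])

    def test_missing_value_names_sample(self):
        with pytest.raises(ClusterTreeError, match="sample 1"):
            compute_overlaps(["a", float("nan")], ["a", "b"])


class TestInProportion:
    @pytest.mark.parametrize(
        "count,size,expected", [(0, 120, 0.0), (120, 120, 1.0), (30, 120, 0.25)]
    )
    def test_direct_ratio(self, count, size, expected):
        assert in_proportion(count, size) == expected

    def test_empty_target_is_invariant_violation(self):
        with pytest.raises(InvariantError):
            in_proportion(0, 0)

    def test_count_exceeding_target_rejected(self):
        with pytest.raises(ClusterTreeError):
            in_proportion(5, 3)


class TestBuildTree:
    def test_single_resolution_has_nodes_no_edges(self):
        tree = build_tree(make_set({1.0: ["1", "1", "2"]}))
        assert len(tree.nodes) == 2 and tree.edges == []
        assert {n.size for n in tree.nodes} == {1, 2}

    def test_toy_moves_no_sample_between_branches(self):
        # 4 samples: A@k2 stays whole; B@k2 splits into B and C at k3.
        tree = build_tree(
            make_set({2.0: ["A", "A", "B", "B"], 3.0: ["A", "A", "B", "C"]}),
            prop_filter=0.0,
        )
        edges = {(e.source, e.target): e for e in tree.edges}
        assert ("2CA", "3CB") not in edges  # no flow from A into B
        assert edges[("2CA", "3CA")].count == 2 and edges[("2CA", "3CA")].in_proportion == 1.0
        assert edges[("2CB", "3CB")].count == 1 and edges[("2CB", "3CB")].in_proportion == 1.0
        assert edges[("2CB", "3CC")].count == 1 and edges[("2CB", "3CC")].in_proportion == 1.0

    def test_thresholds_are_strict_inequalities(self):
        cols = {2.0: ["A", "A", "B", "B"], 3.0: ["A", "A", "B", "C"]}
        # p = 1.0 for all retained edges, so prop_filter=0.6 keeps them all
        assert len(build_tree(make_set(cols), prop_filter=0.6).edges) == 3
        # count 1 is not > 1, so count_filter=1 drops the two split edges
        kept = build_tree(make_set(cols), count_filter=1, prop_filter=0.0).edges
        assert {(e.source, e.target) for e in kept} == {("2CA", "3CA")}

    def test_invalid_thresholds_rejected(self):
        cs = make_set({1.0: ["a", "b"]})
        with pytest.raises(ClusterTreeError):
            build_tree(cs, prop_filter=1.5)
        with pytest.raises(ClusterTreeError):
            build_tree(cs, count_filter=-1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_with_zero_filters(self, seed):
        rng = np.random.default_rng(seed)
        cs = random_clustering_set(rng, n_samples=int(rng.integers(5, 200)))
        tree = build_tree(cs, count_filter=0, prop_filter=0.0)
        for res in cs.resolutions:
            assert sum(n.size for n in tree.nodes_at(res)) == cs.n_samples
        for node in tree.nodes:
            if tree.resolutions.index(node.resolution) == 0:
                continue
            in_edges = tree.in_edges(node.node_id)
            assert sum(e.count for e in in_edges) == node.size
            assert abs(sum(e.in_proportion for e in in_edges) - 1.0) < 1e-12

    def test_monotone_filtering_edge_sets_nested(self):
        rng = np.random.default_rng(7)
        cs = random_clustering_set(rng, n_samples=120, n_resolutions=4)
        previous = None
        for prop in (0.0, 0.1, 0.3, 0.6, 0.9):
            edges = {
                (e.source, e.target) for e in build_tree(cs, prop_filter=prop).edges
            }
            if previous is not None:
                assert edges <= previous
            previous = edges
        previous = None
        for count in (0, 1, 3, 10):
            edges = {
                (e.source, e.target)
                for e in build_tree(cs, count_filter=count, prop_filter=0.0).edges
            }
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_edges_run_to_next_resolution_only_acyclic(self):
        rng = np.random.default_rng(11)
        cs = random_clustering_set(rng, n_samples=80, n_resolutions=5)
        tree = build_tree(cs, prop_filter=0.0)
        for e in tree.edges:
            assert tree.resolution_index(e.target) == tree.resolution_index(e.source) + 1

    def test_deterministic_tables(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        t1 = build_tree(random_clustering_set(rng1, n_samples=90, n_resolutions=4))
        t2 = build_tree(random_clustering_set(rng2, n_samples=90, n_resolutions=4))
        n1, e1 = t1.to_frames()
        n2, e2 = t2.to_frames()
        assert n1.to_csv() == n2.to_csv() and e1.to_csv() == e2.to_csv()


class TestCoreEdges:
    def test_single_in_edge_is_core(self):
        tree = build_tree(make_set({1.0: ["a", "a"], 2.0: ["a", "a"]}))
        (edge,) = tree.edges
        assert edge.is_core

    def test_max_in_proportion_wins(self):
        # target y@2 gets 7 samples from a and 3 from b
        cols = {1.0: ["a"] * 7 + ["b"] * 3, 2.0: ["y"] * 10}
        tree = build_tree(make_set(cols), prop_filter=0.0)
        core = {e.source for e in tree.edges if e.is_core and e.target == "2Cy"}
        assert core == {"1Ca"}

    def test_full_tie_broken_by_smallest_label(self):
        # equal p and equal count into y: label "a" < "b" wins
        cols = {1.0: ["a"] * 5 + ["b"] * 5, 2.0: ["y"] * 10}
        tree = build_tree(make_set(cols), prop_filter=0.0)
        core = [e for e in tree.edges if e.is_core]
        assert len(core) == 1 and tree.node(core[0].source).label == "a"

    def test_tie_on_proportion_prefers_count(self):
        # Directly exercise the selection rule on a constructed edge list.
        from clustertree.core import ClusterEdge, ClusterNode, ClusteringTree

        nodes = [
            ClusterNode(1.0, "a", 40),
            ClusterNode(1.0, "b", 10),
            ClusterNode(1.0, "c", 50),
            ClusterNode(2.0, "y", 100),
        ]
        edges = [
            ClusterEdge("1Ca", "2Cy", count=40, in_proportion=0.5),
            ClusterEdge("1Cb", "2Cy", count=10, in_proportion=0.5),
            ClusterEdge("1Cc", "2Cy", count=50, in_proportion=0.3),
        ]
        tree = ClusteringTree(nodes, edges, (0, 0.0), (1.0, 2.0), 100)
        core_edges(tree)
        winner = [e for e in tree.edges if e.is_core]
        assert len(winner) == 1 and winner[0].source == "1Ca"  # p ties, 40 > 10

    def test_core_subgraph_is_forest(self):
        rng = np.random.default_rng(21)
        cs = random_clustering_set(rng, n_samples=150, n_resolutions=5)
        tree = build_tree(cs, prop_filter=0.0)
        for node in tree.nodes:
            assert sum(e.is_core for e in tree.in_edges(node.node_id)) <= (
                0 if tree.resolution_index(node.node_id) == 0 else 1
            )
            if tree.resolution_index(node.node_id) > 0:
                assert sum(e.is_core for e in tree.in_edges(node.node_id)) == 1


class TestClusteringSetValidation:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ClusterTreeError, match="duplicate"):
            ClusteringSet(("s", "s"), (1.0,), np.array([["a"], ["b"]], dtype=object))

    def test_non_increasing_resolutions_rejected(self):
        with pytest.raises(ClusterTreeError, match="strictly increasing"):
            ClusteringSet(
                ("s0", "s1"), (2.0, 2.0), np.array([["a", "a"], ["b", "b"]], dtype=object)
            )

    def test_missing_assignment_rejected(self):
        with pytest.raises(ClusterTreeError, match="missing assignment"):
            ClusteringSet(("s0", "s1"), (1.0,), np.array([["a"], [None]], dtype=object))
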