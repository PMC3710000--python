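from itertools import combinations

import pytest

from signetmotif import (
    Motif,
    OracleIndex,
    SignedDigraph,
    SearchStats,
    build_path_tree,
    count_matches,
    enumerate_connected_subgraphs,
    find_matches,
    random_query_motifs,
)
from signetmotif.search import esu_partial_count
from tests.conftest import make_random


def brute_connected_sets(g, k):
    out = set()
    for subset in combinations(g.sorted_nodes(), k):
        members = set(subset)
        seen, frontier = {subset[0]}, [subset[0]]
        while frontier:
            u = frontier.pop()
            for v in g.neighbors(u) & members - seen:
                seen.add(v)
                frontier.append(v)
        if len(seen) == k:
            out.add(frozenset(subset))
    return out


class TestEnumeration:
    def test_triangle_single_set(self):
        g = SignedDigraph([("a", "b", 1), ("b", "c", -1), ("c", "a", 1)])
        assert [frozenset(s) for s in enumerate_connected_subgraphs(g, 3)] == [
            frozenset({"a", "b", "c"})
        ]

    def test_star_three_sets(self):
        g = SignedDigraph([("c", "x", 1), ("c", "y", 1), ("c", "z", 1)])
        sets = {frozenset(s) for s in enumerate_connected_subgraphs(g, 3)}
        assert sets == {frozenset({"c", "x", "y"}), frozenset({"c", "x", "z"}),
                        frozenset({"c", "y", "z"})}

    def test_chain_pairs(self):
        g = SignedDigraph([("a", "b", 1), ("b", "c", 1)])
        sets = {frozenset(s) for s in enumerate_connected_subgraphs(g, 2)}
        assert sets == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_k1_yields_every_node(self):
        g = SignedDigraph([("a", "b", 1)], nodes=["z"])
        assert {s[0] for s in enumerate_connected_subgraphs(g, 1)} == {"a", "b", "z"}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            list(enumerate_connected_subgraphs(SignedDigraph(nodes=["a"]), 0))

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_each_connected_set_exactly_once(self, seed, k):
        """ESU yields every weakly connected k-set exactly once (<=8 nodes)."""
        g = make_random(n=8, m=14, seed=seed)
        listed = [frozenset(s) for s in enumerate_connected_subgraphs(g, k)]
        assert len(listed) == len(set(listed)), "duplicate emission"
        assert set(listed) == brute_connected_sets(g, k)


class TestFindMatches:
    def test_whole_graph_is_the_motif(self, negative_loop, negative_loop_motif):
        tree = build_path_tree([negative_loop_motif], 2)
        matches = find_matches(negative_loop, tree)
        assert len(matches) == 1
        assert matches[0].node_set == {"A", "B"}
        assert matches[0].motif_id == "neg2"

    def test_induced_semantics_reject_chord(self, positive_cycle):
        chorded = positive_cycle.copy()
        chorded.add_edge("A", "C", 1)
        m = Motif("cyc", "custom", positive_cycle)
        assert find_matches(chorded, build_path_tree([m], 3)) == []

    def test_match_matrix_consistent_with_discovery_order(self):
        g = make_random(n=12, m=30, seed=4)
        motifs = random_query_motifs(g, 3, 5, seed=9)
        tree = build_path_tree(motifs, 3)
        from signetmotif import all_isomorph_labels, label_of

        by_id = {m.id: m for m in motifs}
        for match in find_matches(g, tree):
            lab = label_of([list(r) for r in match.matrix])
            assert lab in all_isomorph_labels(by_id[match.motif_id].graph)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [3, 4])
    def test_agreement_with_oracle(self, seed, k):
        g = make_random(n=18, m=40, seed=seed)
        motifs = random_query_motifs(g, k, 8, seed=seed + 100)
        if not motifs:
            pytest.skip("no connected k-subgraph sampled")
        index = OracleIndex(g, k)
        tree = build_path_tree(motifs, k)
        found: dict[str, set] = {m.id: set() for m in motifs}
        for match in find_matches(g, tree):
            found[match.motif_id].add(match.node_set)
        for m in motifs:
            assert found[m.id] == index.matches(m), m.id

    def test_same_set_never_matches_two_motifs(self):
        g = make_random(n=15, m=35, seed=2)
        motifs = random_query_motifs(g, 3, 10, seed=3)
        tree = build_path_tree(motifs, 3)
        seen = {}
        for match in find_matches(g, tree):
            assert seen.setdefault(match.node_set, match.motif_id) == match.motif_id

    def test_pruning_never_exceeds_unpruned_visits(self):
        for seed in range(4):
            g = make_random(n=20, m=45, seed=seed)
            motifs = random_query_motifs(g, 3, 3, seed=seed)
            tree = build_path_tree(motifs, 3)
            stats = SearchStats()
            find_matches(g, tree, stats)
            assert stats.partials_visited <= esu_partial_count(g, 3)


class TestCountMatches:
    def test_empty_graph_all_zero(self, negative_loop_motif):
        g = SignedDigraph(nodes=["x", "y"])
        assert count_matches(g, [negative_loop_motif]) == {"neg2": 0}

    def test_motif_equals_graph(self, negative_loop, negative_loop_motif):
        assert count_matches(negative_loop, [negative_loop_motif]) == {"neg2": 1}

    def test_counts_match_oracle(self):
        g = make_random(n=16, m=36, seed=7)
        motifs = random_query_motifs(g, 3, 6, seed=8)
        counts = count_matches(g, motifs)
        index = OracleIndex(g, 3)
        for m in motifs:
            assert counts[m.id] == len(index.matches(m))

    def test_mixed_sizes_in_one_call(self):
        g = make_random(n=14, m=30, seed=5)
        motifs = random_query_motifs(g, 2, 3, seed=1) + \
            random_query_motifs(g, 3, 3, seed=2)
        counts = count_matches(g, motifs)
        assert set(counts) == {m.id for m in motifs}
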