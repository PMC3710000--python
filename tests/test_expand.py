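import pytest

from signetmotif import (
    EdgePath,
    Motif,
    SignedDigraph,
    build_path_tree,
    compress,
    expand_edge,
    expand_match,
    find_matches,
    instantiate,
    read_network,
    structural_properties,
)


@pytest.fixture
def chain_net():
    return read_network("A + B\nB - C\nC + D\n")


class TestExpandEdge:
    def test_unique_cascade_path(self, chain_net):
        paths = expand_edge(chain_net, "A", "D", -1, {"B", "C"})
        assert [p.nodes for p in paths] == [("A", "B", "C", "D")]
        assert paths[0].sign == -1 and paths[0].length == 3

    def test_direct_edge_always_qualifies(self, chain_net):
        g = chain_net.copy()
        g.add_edge("A", "D", -1)
        paths = expand_edge(g, "A", "D", -1, {"B", "C"})
        assert [p.nodes for p in paths] == [("A", "B", "C", "D"), ("A", "D")]

    def test_sign_mismatch_gives_empty(self, chain_net):
        assert expand_edge(chain_net, "A", "D", 1, {"B", "C"}) == []

    def test_internal_nodes_must_be_eliminated(self, chain_net):
        # C not eliminated: the long path is no longer admissible
        assert expand_edge(chain_net, "A", "D", -1, {"B"}) == []

    def test_max_len_cap(self, chain_net):
        assert expand_edge(chain_net, "A", "D", -1, {"B", "C"}, max_len=2) == []

    def test_self_loop_expansion(self):
        g = read_network("A + B\nB - A\n")
        comp = compress(g, protected={"A"})
        paths = expand_edge(g, "A", "A", -1, comp.eliminated)
        assert [p.nodes for p in paths] == [("A", "B", "A")]
        assert paths[0].length == 2

    def test_direct_self_loop(self):
        g = read_network("A - A\n")
        paths = expand_edge(g, "A", "A", -1, frozenset())
        assert [p.nodes for p in paths] == [("A", "A")]

    def test_unknown_node_errors(self, chain_net):
        with pytest.raises(KeyError):
            expand_edge(chain_net, "A", "Q", 1, set())


def _match_for(g, motif):
    tree = build_path_tree([motif], motif.size)
    matches = find_matches(g, tree)
    assert len(matches) == 1
    return matches[0]


class TestInstantiate:
    @pytest.fixture
    def two_edge_match(self):
        g = SignedDigraph([("A", "B", 1), ("B", "A", 1)])
        m = Motif("mutual", "bistable_switch", g)
        return _match_for(g, m), m

    def test_cartesian_product_of_disjoint_paths(self, two_edge_match):
        match, motif = two_edge_match
        expansions = {
            ("A", "B", 1): [EdgePath(("A", "B"), 1),
                            EdgePath(("A", "x1", "B"), 1)],
            ("B", "A", 1): [EdgePath(("B", "A"), 1),
                            EdgePath(("B", "y1", "A"), 1),
                            EdgePath(("B", "y1", "y2", "A"), 1)],
        }
        # y1 repeats across two alternatives of ONE edge (fine);
        # across edges everything is disjoint -> full 2x3 product
        instances = instantiate(match, expansions, motif)
        assert len(instances) == 6

    def test_shared_internal_node_filtered(self, two_edge_match):
        match, motif = two_edge_match
        expansions = {
            ("A", "B", 1): [EdgePath(("A", "X", "B"), 1)],
            ("B", "A", 1): [EdgePath(("B", "X", "A"), 1)],
        }
        assert instantiate(match, expansions, motif) == []
        relaxed = instantiate(match, expansions, motif, allow_shared_internals=True)
        assert len(relaxed) == 1

    def test_empty_expansion_list_yields_no_instances(self, two_edge_match):
        match, motif = two_edge_match
        expansions = {("A", "B", 1): [EdgePath(("A", "B"), 1)], ("B", "A", 1): []}
        assert instantiate(match, expansions, motif) == []

    def test_min_size_flag_filters_direct_only_instances(self):
        g = SignedDigraph([("A", "B", 1), ("B", "A", -1)])
        motif = Motif("neg2", "oscillation", g, min_size=3)
        match = _match_for(g, motif)
        expansions = {
            ("A", "B", 1): [EdgePath(("A", "B"), 1)],
            ("B", "A", -1): [EdgePath(("B", "A"), -1)],
        }
        assert instantiate(match, expansions, motif) == []  # size 2 < 3
        expansions[("B", "A", -1)] = [EdgePath(("B", "w", "A"), -1)]
        kept = instantiate(match, expansions, motif)
        assert len(kept) == 1 and kept[0].size == 3

    def test_missing_expansion_key_errors(self, two_edge_match):
        match, motif = two_edge_match
        with pytest.raises(KeyError):
            instantiate(match, {("A", "B", 1): []}, motif)


class TestStructuralProperties:
    def test_cascade_instance_properties(self, chain_net):
        comp = compress(chain_net, protected={"A", "D"})
        motif = Motif("edge", "custom", SignedDigraph([("u", "v", -1)]))
        match = _match_for(comp.reduced, motif)
        instances = expand_match(match, comp, motif)
        assert len(instances) == 1
        props = structural_properties(instances[0])
        assert props["size"] == 4
        assert props["edges"][0]["sign"] == -1
        assert props["edges"][0]["length"] == 3
        assert props["edges"][0]["path"] == "A>B>C>D"

    def test_self_loop_instance_size_two(self):
        g = read_network("A + B\nB - A\n")
        comp = compress(g, protected={"A"})
        motif = Motif("negself", "oscillation",
                      SignedDigraph([("s", "s", -1)]))
        match = _match_for(comp.reduced, motif)
        instances = expand_match(match, comp, motif)
        assert len(instances) == 1
        props = structural_properties(instances[0])
        assert props["size"] == 2
        assert props["edges"][0]["length"] == 2

    def test_incompressible_instance_all_lengths_one(self):
        g = SignedDigraph([("A", "B", 1), ("B", "A", 1)])
        comp = compress(g, protected=("A", "B"))  # nothing can be eliminated
        assert comp.reduced == g
        motif = Motif("mutual", "bistable_switch", g)
        match = _match_for(comp.reduced, motif)
        instances = expand_match(match, comp, motif)
        assert len(instances) == 1
        assert all(p.length == 1 for _, p in instances[0].paths)
        assert instances[0].size == 2
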