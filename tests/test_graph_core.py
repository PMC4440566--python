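"""Graph data model, edge-list I/O, and elementary operations."""

import itertools

import pytest

from coreperiphery.graph import (
    EditSet,
    Graph,
    apply_edits,
    component_diameter,
    connected_components,
    induced_subgraph,
    read_edge_list,
    write_edge_list,
)
from coreperiphery.synthetic import er_graph

from conftest import NAMED, G


class TestReadEdgeList:
    def test_basic_tsv(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("a\tb\nb\tc\n")
        g = read_edge_list(p)
        assert g.n == 3 and g.m == 2

    def test_reversed_duplicate_collapses(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("a\tb\nb\ta\n")
        assert read_edge_list(p).m == 1

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("a\tb\nc\tc\n")
        with pytest.raises(ValueError, match=":2"):
            read_edge_list(p)

    def test_comments_and_isolated_vertices(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("# comment\na\tb\nlonely\n")
        g = read_edge_list(p)
        assert g.n == 3 and g.degree("lonely") == 0

    def test_sif_dialect(self, tmp_path):
        p = tmp_path / "g.sif"
        p.write_text("a pp b c\nb pp d\n")
        g = read_edge_list(p, dialect="sif")
        assert sorted(map(sorted, g.edges)) == [["a", "b"], ["a", "c"], ["b", "d"]]

    def test_sif_too_few_fields(self, tmp_path):
        p = tmp_path / "g.sif"
        p.write_text("a b\n")
        with pytest.raises(ValueError, match="SIF"):
            read_edge_list(p, dialect="sif")

    def test_round_trip(self, tmp_path):
        g = er_graph(15, 0.3, 42)
        path = tmp_path / "rt.tsv"
        write_edge_list(g, path)
        assert read_edge_list(path) == g


class TestGraphInvariants:
    def test_no_self_loops(self):
        with pytest.raises(ValueError):
            Graph("ab", [("a", "a")])

    def test_edges_unordered(self):
        assert G("ab") == Graph("ab", [("b", "a")])

    def test_immutability_surface(self):
        g = G("ab bc")
        assert isinstance(g.vertices, frozenset)
        assert isinstance(g.edges, frozenset)
        assert isinstance(g.neighbors("b"), frozenset)


class TestComponents:
    def test_two_triangles(self):
        comps = connected_components(NAMED["two_triangles"])
        assert sorted(len(c) for c in comps) == [3, 3]

    def test_empty_graph_on_two_vertices(self):
        assert connected_components(Graph("ab")) == [
            frozenset("a"), frozenset("b")
        ]

    def test_p5_single_component(self):
        assert len(connected_components(NAMED["P5"])) == 1

    def test_deterministic_order(self):
        comps = connected_components(G("dc ab"))
        assert [min(c) for c in comps] == ["a", "c"]


class TestInducedSubgraph:
    def test_c5_to_p3(self):
        sub = induced_subgraph(NAMED["C5"], {"a", "b", "c"})
        assert sub.m == 2 and sub.degree("b") == 2

    def test_empty_selection(self):
        assert induced_subgraph(NAMED["K4"], set()).n == 0

    def test_k4_to_k3(self):
        assert induced_subgraph(NAMED["K4"], {"a", "b", "c"}).m == 3

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown"):
            induced_subgraph(NAMED["K3"], {"a", "z"})


class TestApplyEdits:
    def test_delete_two_adjacent_c5_edges(self):
        e = EditSet(deletions={frozenset("ab"), frozenset("bc")})
        h = apply_edits(NAMED["C5"], e)
        # P4 (c-d-e-a) plus isolated b
        assert h.degree("b") == 0
        assert sorted(len(c) for c in connected_components(h)) == [1, 4]

    def test_identity(self):
        g = NAMED["C5"]
        assert apply_edits(g, EditSet()) == g

    def test_2k2_plus_bridge_is_p4(self):
        h = apply_edits(NAMED["2K2"], EditSet(insertions={frozenset("bc")}))
        assert component_diameter(h, h.vertices) == 3

    def test_insert_existing_edge_error(self):
        with pytest.raises(ValueError, match="insertion"):
            apply_edits(NAMED["K3"], EditSet(insertions={frozenset("ab")}))

    def test_delete_absent_edge_error(self):
        with pytest.raises(ValueError, match="deletion"):
            apply_edits(NAMED["2K2"], EditSet(deletions={frozenset("ac")}))

    @pytest.mark.parametrize("seed", range(5))
    def test_involution_on_random_graphs(self, seed):
        g = er_graph(10, 0.4, seed)
        pairs = sorted(
            frozenset(p) for p in itertools.combinations(g.sorted_vertices(), 2)
        )
        chosen = pairs[seed::4][:6]
        e = EditSet(
            insertions=frozenset(p for p in chosen if p not in g.edges),
            deletions=frozenset(p for p in chosen if p in g.edges),
        )
        assert apply_edits(apply_edits(g, e), e.inverse()) == g

    def test_component_count_monotone_under_single_edits(self):
        g = er_graph(9, 0.2, 3)
        base = len(connected_components(g))
        u, v = next(iter(g.non_edges()))
        more = apply_edits(g, EditSet(insertions={frozenset((u, v))}))
        assert len(connected_components(more)) <= base
        e = next(iter(g.edges))
        fewer = apply_edits(g, EditSet(deletions={e}))
        assert len(connected_components(fewer)) >= base


class TestDiameter:
    def test_values(self):
        assert component_diameter(NAMED["K3"], NAMED["K3"].vertices) == 1
        assert component_diameter(NAMED["P5"], NAMED["P5"].vertices) == 4
        assert component_diameter(NAMED["necktie"], NAMED["necktie"].vertices) == 3

    def test_disconnected_component_error(self):
        with pytest.raises(ValueError, match="connected"):
            component_diameter(NAMED["2K2"], NAMED["2K2"].vertices)
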