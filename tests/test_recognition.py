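"""Recognition of split, split cluster, and monopolar graphs, with certificates."""

import itertools

import pytest

from coreperiphery.graph import Graph, induced_subgraph
from coreperiphery.oracles import (
    SPLIT,
    brute_force_edit,
    graph_from_bits,
    nonisomorphic_graphs,
)
from coreperiphery.recognition import (
    AnnotatedPartition,
    ForbiddenCertificate,
    check_annotated_monopolar,
    check_annotated_split_cluster,
    is_graphical,
    is_monopolar_bruteforce,
    is_split,
    is_split_cluster,
    localize_2K2,
    split_partition,
    splittance,
)

from conftest import NAMED, G


class TestSplittance:
    @pytest.mark.parametrize(
        "degrees,expected",
        [([2, 2, 2, 2, 2], 2), ([1, 1, 1, 1], 1), ([2, 2, 2], 0), ([], 0)],
    )
    def test_known_values(self, degrees, expected):
        assert splittance(degrees) == expected

    def test_matches_brute_force_on_c5_and_2k2(self):
        for name in ("C5", "2K2"):
            g = NAMED[name]
            assert splittance(g.degree_sequence()) == \
                brute_force_edit(g, SPLIT).objective

    def test_non_graphical_rejected(self):
        with pytest.raises(ValueError, match="graphical"):
            splittance([3, 1, 1])
        assert not is_graphical([2, 1])  # odd sum

    def test_split_partition_cost_equals_splittance(self):
        for n in range(1, 6):
            for bits in nonisomorphic_graphs(n):
                g = graph_from_bits(n, bits)
                _, cost = split_partition(g)
                assert cost == splittance(g.degree_sequence())


class TestIsSplit:
    def test_c4_certificate(self):
        ok, cert, part = is_split(NAMED["C4"])
        assert not ok and cert.kind == "C4" and cert.verify(NAMED["C4"])

    def test_single_vertex(self):
        ok, cert, part = is_split(NAMED["K1"])
        assert ok and part.covers(NAMED["K1"])

    def test_p4_is_split(self):
        ok, _, part = is_split(NAMED["P4"])
        assert ok
        # witnessing partition: core is a clique, periphery independent
        g = NAMED["P4"]
        assert all(g.has_edge(u, v) for u, v in itertools.combinations(part.core, 2))
        assert not any(
            g.has_edge(u, v) for u, v in itertools.combinations(part.periphery, 2)
        )

    def test_agrees_with_zero_splittance_small(self):
        for n in range(1, 6):
            for bits in nonisomorphic_graphs(n):
                g = graph_from_bits(n, bits)
                assert is_split(g)[0] == (splittance(g.degree_sequence()) == 0)


class TestIsSplitCluster:
    @pytest.mark.parametrize(
        "name,member,kind",
        [
            ("P5", False, "P5"),
            ("two_triangles", True, None),
            ("bowtie", False, "bowtie"),
            ("necktie", False, "necktie"),
            ("C4", False, "C4"),
            ("C5", False, "C5"),
            ("star", True, None),
            ("K1", True, None),
        ],
    )
    def test_examples(self, name, member, kind):
        ok, cert = is_split_cluster(NAMED[name])
        assert ok == member
        if not member:
            assert cert.kind == kind and cert.verify(NAMED[name])

    def test_all_returned_certificates_verify(self):
        for n in range(1, 7):
            for bits in nonisomorphic_graphs(n):
                g = graph_from_bits(n, bits)
                ok, cert = is_split_cluster(g)
                if not ok:
                    assert cert.kind in ("C4", "C5", "P5", "necktie", "bowtie")
                    assert cert.verify(g)


class TestLocalize2K2:
    def test_p5_direct(self):
        g = NAMED["P5"]
        p1, p2, v = localize_2K2(g, ("a", "b"), ("d", "e"))
        assert v == "c" and set(p1) == {"a", "b"} and set(p2) == {"d", "e"}

    def test_p6_distance_case(self):
        g = NAMED["P6"]
        p1, p2, v = localize_2K2(g, ("a", "b"), ("e", "f"))
        cert = ForbiddenCertificate("2K2", tuple(p1) + tuple(p2))
        assert cert.verify(g)
        assert v not in set(p1) | set(p2)
        assert g.neighbors(v) & set(p1) and g.neighbors(v) & set(p2)

    def test_necktie_unique_2k2(self):
        g = NAMED["necktie"]
        p1, p2, v = localize_2K2(g, ("a", "b"), ("c", "d"))
        assert v == "v"
        assert {frozenset(p1), frozenset(p2)} == {frozenset("ab"), frozenset("cd")}

    def test_not_a_2k2_rejected(self):
        with pytest.raises(ValueError, match="2K2"):
            # edges of P4 a-b-c-d, but b-c joins them: not induced
            localize_2K2(NAMED["P4"], ("a", "b"), ("c", "d"))

    def test_different_components_rejected(self):
        g = G("ab cd ef", extra_vertices="")
        with pytest.raises(ValueError):
            localize_2K2(g, ("a", "b"), ("c", "d"))


class TestAnnotatedChecks:
    def test_periphery_edge_violation(self):
        g = NAMED["K2"]
        p = AnnotatedPartition(core=frozenset(), periphery=frozenset("ab"))
        ok, viol = check_annotated_split_cluster(g, p)
        assert not ok and viol[0] == "edge"

    def test_p3_endpoints_in_core_split_cluster_vs_monopolar(self):
        g = NAMED["P3"]  # a-b-c
        p = AnnotatedPartition(core=frozenset("ac"), periphery=frozenset("b"))
        # split cluster: the two core endpoints of the P3 must be adjacent
        ok, viol = check_annotated_split_cluster(g, p)
        assert not ok and viol[0] == "P3"
        # monopolar: the P3 middle is in I, so the core is P3-free
        ok, viol = check_annotated_monopolar(g, p)
        assert ok

    def test_p3_entirely_in_core_rejected_monopolar(self):
        g = NAMED["P3"]
        p = AnnotatedPartition(core=frozenset("abc"), periphery=frozenset())
        assert not check_annotated_monopolar(g, p)[0]

    def test_empty_graph_any_partition(self):
        g = Graph("ab")
        p = AnnotatedPartition(core=frozenset("a"), periphery=frozenset("b"))
        assert check_annotated_split_cluster(g, p)[0]
        assert check_annotated_monopolar(g, p)[0]

    def test_clique_all_core(self):
        g = NAMED["K4"]
        p = AnnotatedPartition(core=g.vertices, periphery=frozenset())
        assert check_annotated_monopolar(g, p)[0]

    def test_split_cluster_implies_monopolar_same_partition(self):
        for n in range(1, 6):
            for bits in nonisomorphic_graphs(n):
                g = graph_from_bits(n, bits)
                vs = g.sorted_vertices()
                for r in range(len(vs) + 1):
                    for peri in itertools.combinations(vs, r):
                        p = AnnotatedPartition(
                            core=g.vertices - set(peri), periphery=frozenset(peri)
                        )
                        if check_annotated_split_cluster(g, p)[0]:
                            assert check_annotated_monopolar(g, p)[0]


class TestMonopolarBruteforce:
    def test_w4_not_monopolar(self):
        assert not is_monopolar_bruteforce(NAMED["W4"])[0]

    def test_c5_monopolar_with_witness(self):
        ok, part = is_monopolar_bruteforce(NAMED["C5"])
        assert ok
        assert check_annotated_monopolar(NAMED["C5"], part)[0]

    def test_k3_all_core(self):
        ok, part = is_monopolar_bruteforce(NAMED["K3"])
        assert ok

    def test_size_guard(self):
        g = Graph([f"v{i}" for i in range(25)])
        with pytest.raises(ValueError, match="vertices"):
            is_monopolar_bruteforce(g, max_n=20)
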