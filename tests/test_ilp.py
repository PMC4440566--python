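"""ILP formulations: examples, cut validity, variable fixing, oracle agreement."""

import itertools

import pytest

from coreperiphery.graph import Graph, apply_edits
from coreperiphery.ilp import (
    IlpConfig,
    IlpModel,
    fix_variables_obs1,
    separate_cuts,
    solve_ce,
    solve_me_partition,
    solve_sce_forbidden,
    solve_sce_partition,
)
from coreperiphery.oracles import exact_edit_value
from coreperiphery.recognition import (
    AnnotatedPartition,
    check_annotated_monopolar,
    is_split_cluster,
)
from coreperiphery.synthetic import er_graph

from conftest import NAMED, G

CFG = IlpConfig(warm_start=False)


class TestSceExamples:
    @pytest.mark.parametrize("solver", [solve_sce_forbidden, solve_sce_partition])
    def test_c5_needs_two_edits(self, solver):
        assert solver(NAMED["C5"], CFG).objective == 2

    @pytest.mark.parametrize("solver", [solve_sce_forbidden, solve_sce_partition])
    def test_p5_needs_one_edit(self, solver):
        assert solver(NAMED["P5"], CFG).objective == 1

    def test_split_cluster_graph_zero_edits(self):
        # necktie minus the far path edge is a split graph
        g = G("ab av bv vc")
        res = solve_sce_forbidden(g, CFG)
        assert res.objective == 0 and res.edits.size == 0

    def test_star_partition_roles(self):
        res = solve_sce_partition(NAMED["star"], CFG)
        assert res.objective == 0
        ((core, peri),) = res.partition.clusters
        assert core == frozenset("a") and peri == frozenset("xyz")

    def test_solution_passes_recognizer(self):
        for seed in range(3):
            g = er_graph(8, 0.4, seed)
            res = solve_sce_partition(g, CFG)
            assert is_split_cluster(apply_edits(g, res.edits))[0]
            assert res.optimal


class TestMeExamples:
    def test_p5_is_monopolar(self):
        res = solve_me_partition(NAMED["P5"], CFG)
        assert res.objective == 0

    def test_w4_needs_an_edit(self):
        assert solve_me_partition(NAMED["W4"], CFG).objective >= 1

    def test_cluster_graph_zero(self):
        assert solve_me_partition(NAMED["two_triangles"], CFG).objective == 0

    def test_monopolar_witness_valid(self):
        g = er_graph(9, 0.3, 5)
        res = solve_me_partition(g, CFG)
        edited = apply_edits(g, res.edits)
        part = AnnotatedPartition(
            core=edited.vertices - res.partition.shared_periphery,
            periphery=res.partition.shared_periphery,
        )
        assert check_annotated_monopolar(edited, part)[0]


class TestCeExamples:
    def test_p3(self):
        assert solve_ce(NAMED["P3"], CFG).objective == 1

    def test_disjoint_cliques(self):
        assert solve_ce(NAMED["two_triangles"], CFG).objective == 0

    def test_p5(self):
        assert solve_ce(NAMED["P5"], CFG).objective == 2

    def test_size1_clusters_become_periphery(self):
        g = G("ab bc ac", extra_vertices="z")
        res = solve_ce(g, CFG)
        assert res.partition.shared_periphery == frozenset("z")


class TestObs1Fixing:
    def test_star_fixes_leaves(self):
        g = NAMED["star"]
        m = fix_variables_obs1(g, IlpModel(g, core_vars=True))
        assert m.fixed_assignments[("c", "x")] == 0
        assert m.fixed_assignments[("e", "x", "y")] == 0
        assert ("c", "a") not in m.fixed_assignments

    def test_k2_nothing_fixed(self):
        g = NAMED["K2"]
        m = fix_variables_obs1(g, IlpModel(g, core_vars=True))
        assert not m.fixed_assignments

    def test_triangle_nothing_fixed(self):
        m = fix_variables_obs1(NAMED["K3"], IlpModel(NAMED["K3"], core_vars=True))
        assert not m.fixed_assignments

    def test_fixing_preserves_optimum(self):
        # pendant vertices everywhere: star and a lollipop
        for g in (NAMED["star"], G("ab bc ac cd"), NAMED["P4"]):
            with_fix = solve_sce_partition(g, IlpConfig(warm_start=False,
                                                        obs1_fixing=True))
            without = solve_sce_partition(g, IlpConfig(warm_start=False,
                                                       obs1_fixing=False))
            assert with_fix.objective == without.objective


def _feasible_integral_assignments(g, problem):
    """All 0/1 assignments satisfying the base partition-model constraints
    (independent periphery + the full P3 constraint family)."""
    m = IlpModel(g, core_vars=True)
    vs = m.vertices
    for e_bits in itertools.product([0, 1], repeat=len(m.pairs)):
        h = Graph(vs, [p for p, b in zip(m.pairs, e_bits) if b])
        for c_bits in itertools.product([0, 1], repeat=len(vs)):
            core = frozenset(v for v, b in zip(vs, c_bits) if b)
            part = AnnotatedPartition(core=core, periphery=h.vertices - core)
            from coreperiphery.recognition import (
                check_annotated_monopolar,
                check_annotated_split_cluster,
            )
            check = (check_annotated_split_cluster if problem == "sce"
                     else check_annotated_monopolar)
            if check(h, part)[0]:
                vals = {("e",) + p: float(b) for p, b in zip(m.pairs, e_bits)}
                vals.update(
                    {("c", v): float(b) for v, b in zip(vs, c_bits)}
                )
                yield vals


class TestSeparateCuts:
    def test_integral_feasible_solution_yields_no_cuts(self):
        # validity: no integral solution satisfying the model is cut off
        g = NAMED["C4"]
        for problem, kinds in (("sce", ["P3", "C4", "P5"]), ("me", ["P3", "W4"])):
            for vals in _feasible_integral_assignments(g, problem):
                for kind in kinds:
                    assert separate_cuts(
                        vals, g, kind, min_violation=1e-6, problem=problem
                    ) == []

    def test_p3_cut_with_violation_one(self):
        g = NAMED["P3"]  # a-b-c in the input
        vals = {("e", "a", "b"): 1.0, ("e", "b", "c"): 1.0, ("e", "a", "c"): 0.0,
                ("c", "a"): 1.0, ("c", "b"): 0.0, ("c", "c"): 1.0}
        cuts = separate_cuts(vals, g, "P3", problem="sce")
        assert len(cuts) == 1 and cuts[0].violation == pytest.approx(1.0)

    def test_c4_fractional_violation_arithmetic(self):
        g = NAMED["C4"]
        vals = {("e",) + tuple(sorted(p)): 0.5
                for p in itertools.combinations("abcd", 2)}
        # lhs = 4*(1-0.5) + 2*0.5 = 3 -> violation 1 - 3 = -2: no cut
        assert separate_cuts(vals, g, "C4", min_violation=0.3) == []
        vals = {k: (0.9 if k in {("e", "a", "b"), ("e", "b", "c"),
                                 ("e", "c", "d"), ("e", "a", "d")} else 0.4)
                for k in vals}
        # lhs = 4*0.1 + 2*0.4 = 1.2 -> violation -0.2: still valid
        assert separate_cuts(vals, g, "C4", min_violation=0.3) == []
        vals = {k: (1.0 if k in {("e", "a", "b"), ("e", "b", "c"),
                                 ("e", "c", "d"), ("e", "a", "d")} else 0.0)
                for k in vals}
        # the C4 itself: lhs = 0 -> violation 1
        cuts = separate_cuts(vals, g, "C4", min_violation=0.3)
        assert len(cuts) == 1 and cuts[0].violation == pytest.approx(1.0)

    def test_cap_and_ordering(self):
        g = er_graph(7, 0.6, 11)
        vals = {("e",) + tuple(sorted(p)): 0.0
                for p in itertools.combinations(g.sorted_vertices(), 2)}
        vals.update({("c", v): 0.0 for v in g.sorted_vertices()})
        cuts = separate_cuts(vals, g, "P3", max_cuts=3, min_violation=0.1,
                             problem="sce")
        assert len(cuts) <= 3
        assert all(c1.violation >= c2.violation
                   for c1, c2 in zip(cuts, cuts[1:]))


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_solvers_match_dp_on_er(self, seed):
        g = er_graph(8, [0.15, 0.35, 0.55][seed % 3], 400 + seed)
        sce = exact_edit_value(g, "sce")
        assert solve_sce_forbidden(g, CFG).objective == sce
        assert solve_sce_partition(g, CFG).objective == sce
        me = exact_edit_value(g, "me")
        assert solve_me_partition(g, CFG).objective == me
        ce = exact_edit_value(g, "ce")
        assert solve_ce(g, CFG).objective == ce
        assert me <= sce <= ce

    def test_cuts_do_not_change_optimum(self):
        g = er_graph(9, 0.4, 77)
        on = solve_sce_partition(g, IlpConfig(warm_start=False, cuts=True))
        off = solve_sce_partition(g, IlpConfig(warm_start=False, cuts=False))
        assert on.objective == off.objective

    def test_warm_start_bound_does_not_change_optimum(self):
        g = er_graph(9, 0.35, 78)
        warm = solve_sce_partition(
            g, IlpConfig(warm_start=True, warm_start_steps=500,
                         warm_start_restarts=3)
        )
        cold = solve_sce_partition(g, CFG)
        assert warm.objective == cold.objective
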