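"""Exact editing solvers as mixed-integer programs (HiGHS via scipy).

Two formulations for split cluster editing:

* *forbidden-subgraph*: binary edge variables only; constraints demand that
  every forbidden induced subgraph (C4, C5, P5, necktie, bowtie) loses or
  gains at least one edge.  Constraints are generated by rows: solve, run the
  recognizer on the integral candidate, add the violated constraint, delete
  one certificate vertex and search again (up to n constraints per round),
  repeat until the recognizer accepts.  Optional strengthenings: right-hand
  side 2 for a C5, and the half-coefficient P5 inequality.

* *partition-variable*: additional binary core indicators c_u.  Independent-
  set constraints c_u + c_v + (1 - e_uv) >= 1 for all pairs keep the
  periphery edge-free; P3 constraints force core vertices of one component
  into a clique (split cluster editing) or the whole core into a cluster
  graph (monopolar editing).  P3 constraints for triples inducing a P3 in the
  input are added up front, the rest lazily; forbidden-subgraph inequalities
  (C4/P5 and W4) are separated as cutting planes on the LP relaxation.

Cluster editing uses edge variables with lazy P3 (triangle) inequalities.

Degree-one vertices whose neighbor has larger degree can be fixed to the
periphery with all their non-incident insertions forbidden - there is always
an optimal solution of that shape - which shrinks the model considerably on
periphery-heavy graphs.

The backend has no lazy-constraint callbacks, so row generation is an
iterative re-solve; returned solutions are nevertheless feasible and, absent
a time limit, optimal.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import EditSet, Graph, apply_edits, connected_components, induced_subgraph
from .recognition import (
    AnnotatedPartition,
    ForbiddenCertificate,
    CERTIFICATE_PATTERNS,
    check_annotated_monopolar,
    check_annotated_split_cluster,
    is_split_cluster,
    split_cluster_partition,
)
from .results import CorePeripheryPartition, SolveResult

__all__ = [
    "IlpConfig",
    "IlpModel",
    "Cut",
    "solve_sce_forbidden",
    "solve_sce_partition",
    "solve_me_partition",
    "solve_ce",
    "fix_variables_obs1",
    "separate_cuts",
]


@dataclass(frozen=True)
class IlpConfig:
    """Solver configuration shared by all formulations."""

    cuts: bool = True
    time_limit: Optional[float] = None
    warm_start: bool = True  # heuristic upper bound from a short annealing run
    warm_start_steps: int = 2000
    warm_start_restarts: int = 10
    obs1_fixing: bool = True
    max_cut_rounds: int = 10
    max_cuts: int = 500
    min_violation: float = 0.3
    seed: int = 0


@dataclass(frozen=True)
class Cut:
    """A valid inequality sum(coefs * var) >= lb over named variables
    ('e', u, v) and ('c', u)."""

    coefs: tuple
    lb: float
    violation: float = 0.0


class IlpModel:
    """Binary edge variables e_uv for every unordered vertex pair, plus core
    indicators c_u for the partition formulations.

    The objective sum_{uv in E}(1 - e_uv) + sum_{uv not in E} e_uv counts the
    edits; fixed assignments (variable bounds) are honored by every solve.
    """

    def __init__(self, g: Graph, core_vars: bool = False):
        self.graph = g
        self.core_vars = core_vars
        self.vertices = g.sorted_vertices()
        self.pairs = [tuple(p) for p in itertools.combinations(self.vertices, 2)]
        self.pair_idx = {frozenset(p): i for i, p in enumerate(self.pairs)}
        nv = len(self.pairs) + (len(self.vertices) if core_vars else 0)
        self.core_idx = (
            {v: len(self.pairs) + i for i, v in enumerate(self.vertices)}
            if core_vars
            else {}
        )
        self.nvars = nv
        self.obj = np.zeros(nv)
        for i, p in enumerate(self.pairs):
            self.obj[i] = -1.0 if frozenset(p) in g.edges else 1.0
        self.obj_const = float(g.m)
        self.lb = np.zeros(nv)
        self.ub = np.ones(nv)
        self.fixed_assignments: dict[tuple, int] = {}
        # constraint rows in sparse triplet form
        self._rows: list[dict[int, float]] = []
        self._lbs: list[float] = []
        self.solver_log: dict = {"rounds": 0, "cuts_added": 0, "lazy_added": 0}

    # -- variables ---------------------------------------------------------
    def evar(self, u: str, v: str) -> int:
        return self.pair_idx[frozenset((u, v))]

    def cvar(self, u: str) -> int:
        return self.core_idx[u]

    def var_index(self, key: tuple) -> int:
        if key[0] == "e":
            return self.evar(key[1], key[2])
        if key[0] == "c":
            return self.cvar(key[1])
        raise KeyError(key)

    def fix(self, key: tuple, value: int) -> None:
        i = self.var_index(key)
        self.lb[i] = self.ub[i] = float(value)
        self.fixed_assignments[key] = value

    # -- constraints -------------------------------------------------------
    def add_row(self, coefs: dict[int, float], lb: float) -> None:
        self._rows.append(coefs)
        self._lbs.append(lb)

    def add_cut(self, cut: Cut) -> None:
        self.add_row(
            {self.var_index(k): c for k, c in cut.coefs}, cut.lb
        )

    def n_constraints(self) -> int:
        return len(self._rows)

    def forbidden_subgraph_row(
        self, cert: ForbiddenCertificate, rhs: int = 1
    ) -> tuple[dict[int, float], float]:
        """Constraint of type: the solution differs from this induced subgraph
        in at least ``rhs`` pairs."""
        pattern = CERTIFICATE_PATTERNS[cert.kind]
        vs = cert.vertices
        coefs: dict[int, float] = {}
        const = 0.0
        for i, j in itertools.combinations(range(len(vs)), 2):
            idx = self.evar(vs[i], vs[j])
            if (i, j) in pattern or (j, i) in pattern:
                coefs[idx] = coefs.get(idx, 0.0) - 1.0
                const += 1.0
            else:
                coefs[idx] = coefs.get(idx, 0.0) + 1.0
        return coefs, rhs - const

    def p5_strengthened_row(self, p5: tuple) -> tuple[dict[int, float], float]:
        """The half-coefficient P5 inequality for the ordered path u-v-w-x-y:
        deleting a path edge counts 1, most chord insertions only 1/2, and the
        end-pair insertion (which creates a C5) is omitted."""
        u, v, w, x, y = p5
        coefs: dict[int, float] = {}
        const = 0.0
        for a, b in ((u, v), (v, w), (w, x), (x, y)):  # bar-e terms
            coefs[self.evar(a, b)] = -1.0
            const += 1.0
        for a, b, c in ((u, w, 0.5), (v, x, 1.0), (w, y, 0.5), (x, u, 0.5), (y, v, 0.5)):
            coefs[self.evar(a, b)] = coefs.get(self.evar(a, b), 0.0) + c
        return coefs, 1.0 - const

    # -- solving -----------------------------------------------------------
    def _constraint_matrix(self) -> Optional[LinearConstraint]:
        if not self._rows:
            return None
        data, ri, ci = [], [], []
        for r, row in enumerate(self._rows):
            for c, coef in row.items():
                data.append(coef)
                ri.append(r)
                ci.append(c)
        A = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(self._rows), self.nvars)
        )
        return LinearConstraint(A, lb=np.array(self._lbs), ub=np.inf)

    def solve(
        self, relax: bool = False, time_limit: Optional[float] = None
    ):
        """Solve the current model; returns (x, objective, proven_optimal)."""
        cons = self._constraint_matrix()
        integrality = np.zeros(self.nvars) if relax else np.ones(self.nvars)
        options = {}
        if time_limit is not None:
            options["time_limit"] = max(time_limit, 0.01)
        res = milp(
            c=self.obj,
            constraints=cons if cons is not None else [],
            integrality=integrality,
            bounds=Bounds(self.lb, self.ub),
            options=options,
        )
        if res.x is None:
            raise RuntimeError(f"MIP solve failed: {res.message}")
        self.solver_log["rounds"] += 1
        return res.x, self.obj_const + float(self.obj @ res.x), res.status == 0

    def solution_graph(self, x: np.ndarray) -> Graph:
        edges = [p for i, p in enumerate(self.pairs) if x[i] > 0.5]
        return Graph(self.vertices, edges)

    def core_set(self, x: np.ndarray) -> frozenset:
        return frozenset(v for v in self.vertices if x[self.core_idx[v]] > 0.5)


# -- Observation-1 variable fixing -----------------------------------------

def fix_variables_obs1(g: Graph, m: IlpModel) -> IlpModel:
    """Fix every degree-one vertex u whose sole neighbor v has degree > 1 to
    the periphery (c_u = 0) and forbid all insertions at u (e_uw = 0 for
    w not in {u, v}); some optimal solution always has this shape."""
    if not m.core_vars:
        raise ValueError("Observation-1 fixing applies to partition models")
    for u in m.vertices:
        if g.degree(u) != 1:
            continue
        (v,) = g.neighbors(u)
        if g.degree(v) <= 1:
            continue
        m.fix(("c", u), 0)
        for w in m.vertices:
            if w not in (u, v) and frozenset((u, w)) not in g.edges:
                m.fix(("e", u, w), 0)
    return m


# -- pattern enumeration for cutting planes --------------------------------

def _induced_p3s(g: Graph) -> list[tuple]:
    out = []
    for v in g.sorted_vertices():
        nb = sorted(g.neighbors(v))
        for u, w in itertools.combinations(nb, 2):
            if not g.has_edge(u, w):
                out.append((u, v, w))
    return out


def _induced_c4s(g: Graph) -> list[tuple]:
    out = []
    vs = g.sorted_vertices()
    for i, u in enumerate(vs):
        for v in vs[i + 1:]:
            if g.has_edge(u, v):
                continue
            common = sorted(g.neighbors(u) & g.neighbors(v))
            for x, y in itertools.combinations(common, 2):
                if not g.has_edge(x, y) and u < min(x, y):
                    out.append((u, x, v, y))
    return out


def _induced_p5s(g: Graph) -> list[tuple]:
    out = []
    for a in g.sorted_vertices():
        for b in sorted(g.neighbors(a)):
            for c in sorted(g.neighbors(b)):
                if c == a or g.has_edge(a, c):
                    continue
                for d in sorted(g.neighbors(c)):
                    if d in (a, b) or g.has_edge(a, d) or g.has_edge(b, d):
                        continue
                    for e_ in sorted(g.neighbors(d)):
                        if e_ in (a, b, c) or g.has_edge(e_, a) \
                           or g.has_edge(e_, b) or g.has_edge(e_, c):
                            continue
                        if a < e_:  # each path once
                            out.append((a, b, c, d, e_))
    return out


def _induced_w4s(g: Graph) -> list[tuple]:
    out = []
    for h in g.sorted_vertices():
        nb = sorted(g.neighbors(h))
        if len(nb) < 4:
            continue
        sub = induced_subgraph(g, nb)
        for cyc in _induced_c4s(sub):
            out.append((h,) + cyc)
    return out


_PATTERN_ENUMERATORS = {
    "P3": _induced_p3s,
    "C4": _induced_c4s,
    "P5": _induced_p5s,
    "W4": _induced_w4s,
}


def separate_cuts(
    fractional_values: dict,
    g: Graph,
    kind: str,
    max_cuts: int = 500,
    min_violation: float = 0.3,
    problem: str = "sce",
) -> list[Cut]:
    """Inequalities of the requested family violated by at least
    ``min_violation`` under the fractional values, most-violated first,
    truncated to ``max_cuts``.

    ``fractional_values`` maps ('e', u, v) and ('c', u) keys to [0, 1].
    Candidate tuples come from the pattern index of the input graph ``g``
    (for P3 partition cuts: all triples whose two path edges have positive
    fractional value).
    """

    def ev(u, v):
        return fractional_values[("e",) + tuple(sorted((u, v)))]

    def cv(u):
        return fractional_values[("c", u)]

    cuts: list[Cut] = []
    if kind == "P3":
        vs = g.sorted_vertices()
        for v in vs:
            for u, w in itertools.combinations((x for x in vs if x != v), 2):
                if ev(u, v) <= 0 or ev(v, w) <= 0:
                    continue
                # lhs of (6)/(7): bar-e_uv + bar-e_vw + e_uw + bar-c terms
                lhs = (1 - ev(u, v)) + (1 - ev(v, w)) + ev(u, w) \
                    + (1 - cv(u)) + (1 - cv(w))
                coefs = [
                    (("e",) + tuple(sorted((u, v))), -1.0),
                    (("e",) + tuple(sorted((v, w))), -1.0),
                    (("e",) + tuple(sorted((u, w))), 1.0),
                    (("c", u), -1.0),
                    (("c", w), -1.0),
                ]
                const = 4.0
                if problem == "me":
                    lhs += 1 - cv(v)
                    coefs.append((("c", v), -1.0))
                    const = 5.0
                viol = 1.0 - lhs
                if viol >= min_violation:
                    cuts.append(Cut(tuple(coefs), 1.0 - const, viol))
    else:
        rhs = {"C4": 1.0, "P5": 1.0, "W4": 1.0}[kind]
        for tup in _PATTERN_ENUMERATORS[kind](g):
            if kind == "P5":
                # strengthened half-coefficient inequality
                u, v, w, x, y = tup
                lhs = sum(1 - ev(a, b) for a, b in ((u, v), (v, w), (w, x), (x, y)))
                lhs += 0.5 * ev(u, w) + ev(v, x) + 0.5 * ev(w, y) \
                    + 0.5 * ev(x, u) + 0.5 * ev(y, v)
                coefs = [(("e",) + tuple(sorted(p)), -1.0)
                         for p in ((u, v), (v, w), (w, x), (x, y))]
                for a, b, cf in ((u, w, 0.5), (v, x, 1.0), (w, y, 0.5),
                                 (x, u, 0.5), (y, v, 0.5)):
                    coefs.append((("e",) + tuple(sorted((a, b))), cf))
                viol = 1.0 - lhs
                if viol >= min_violation:
                    cuts.append(Cut(tuple(coefs), 1.0 - 4.0, viol))
                continue
            pattern = CERTIFICATE_PATTERNS[kind]
            lhs = 0.0
            coefs = []
            const = 0.0
            for i, j in itertools.combinations(range(len(tup)), 2):
                val = ev(tup[i], tup[j])
                key = ("e",) + tuple(sorted((tup[i], tup[j])))
                if (i, j) in pattern or (j, i) in pattern:
                    lhs += 1 - val
                    coefs.append((key, -1.0))
                    const += 1.0
                else:
                    lhs += val
                    coefs.append((key, 1.0))
            viol = rhs - lhs
            if viol >= min_violation:
                cuts.append(Cut(tuple(coefs), rhs - const, viol))
    cuts.sort(key=lambda c: -c.violation)
    return cuts[:max_cuts]


# -- shared solver scaffolding ---------------------------------------------

class _Deadline:
    def __init__(self, limit: Optional[float]):
        self.t0 = time.monotonic()
        self.limit = limit

    def remaining(self) -> Optional[float]:
        if self.limit is None:
            return None
        return self.limit - (time.monotonic() - self.t0)

    def exceeded(self) -> bool:
        r = self.remaining()
        return r is not None and r <= 0


def _values_dict(m: IlpModel, x: np.ndarray) -> dict:
    vals = {("e",) + p: float(x[i]) for i, p in enumerate(m.pairs)}
    if m.core_vars:
        vals.update({("c", v): float(x[m.core_idx[v]]) for v in m.vertices})
    return vals


def _warm_start_bound(g: Graph, problem: str, cfg: IlpConfig, m: IlpModel) -> None:
    """Add the annealing objective as a valid upper-bound constraint."""
    from .annealing import AnnealConfig, anneal_me, anneal_sce

    acfg = AnnealConfig(
        steps=cfg.warm_start_steps,
        restarts=cfg.warm_start_restarts,
        seed=cfg.seed,
    )
    h = anneal_sce(g, acfg) if problem == "sce" else anneal_me(g, acfg)
    # objective = obj_const + obj @ x <= h.objective
    m.add_row(
        {i: -c for i, c in enumerate(m.obj) if c},
        -(h.objective - m.obj_const),
    )
    m.solver_log["warm_start_bound"] = h.objective


def _lp_cut_phase(m: IlpModel, g: Graph, kinds: list[str], problem: str,
                  cfg: IlpConfig, deadline: _Deadline) -> None:
    for _ in range(cfg.max_cut_rounds):
        if deadline.exceeded():
            return
        x, _, _ = m.solve(relax=True, time_limit=deadline.remaining())
        vals = _values_dict(m, x)
        added = 0
        for kind in kinds:
            for cut in separate_cuts(
                vals, g, kind,
                max_cuts=cfg.max_cuts, min_violation=cfg.min_violation,
                problem=problem,
            ):
                m.add_cut(cut)
                added += 1
        m.solver_log["cuts_added"] += added
        if added == 0:
            return


def _trivial_result(g: Graph, problem: str, solver: str) -> Optional[SolveResult]:
    if g.n > 1:
        return None
    if problem == "sce":
        parts = tuple((frozenset(g.vertices), frozenset()) for _ in range(g.n))
        partition = CorePeripheryPartition(clusters=parts, graph=g)
    else:
        partition = CorePeripheryPartition(
            clusters=tuple(
                (frozenset({v}), frozenset()) for v in g.vertices
            ),
            mode="shared", graph=g,
        )
    return SolveResult(
        edits=EditSet(), objective=0, partition=partition, optimal=True,
        provenance={"solver": solver, "trivial": True},
    )


# -- SCE: forbidden-subgraph formulation -----------------------------------

def solve_sce_forbidden(g: Graph, cfg: IlpConfig = IlpConfig()) -> SolveResult:
    """Optimal split cluster editing via the forbidden-subgraph ILP with row
    generation; with ``cfg.cuts`` the C5 rows get right-hand side 2 and every
    P5 also contributes the strengthened half-coefficient inequality."""
    trivial = _trivial_result(g, "sce", "sce_forbidden")
    if trivial:
        return trivial
    deadline = _Deadline(cfg.time_limit)
    m = IlpModel(g, core_vars=False)
    if cfg.warm_start:
        _warm_start_bound(g, "sce", cfg, m)
    best = None
    while True:
        x, obj, proven = m.solve(time_limit=deadline.remaining())
        cand = m.solution_graph(x)
        best = (x, obj)
        # add up to n rows: find certificate, constrain it, drop one vertex
        h = cand
        added = 0
        first_cert = None
        while added < g.n:
            ok, cert = is_split_cluster(h)
            if ok:
                break
            if first_cert is None:
                first_cert = cert
            rhs = 2 if (cfg.cuts and cert.kind == "C5") else 1
            m.add_row(*m.forbidden_subgraph_row(cert, rhs=rhs))
            if cfg.cuts and cert.kind == "P5":
                m.add_row(*m.p5_strengthened_row(cert.vertices))
            added += 1
            h = induced_subgraph(h, set(h.vertices) - {cert.vertices[0]})
        m.solver_log["lazy_added"] += added
        if first_cert is None:
            partition = CorePeripheryPartition(
                clusters=tuple(
                    (p.core, p.periphery) for p in split_cluster_partition(cand)
                ),
                mode="per_cluster", graph=cand,
            )
            edits = _edits_between(g, cand)
            return SolveResult(
                edits=edits, objective=edits.size, partition=partition,
                optimal=proven and not deadline.exceeded(),
                provenance={"solver": "sce_forbidden",
                            "formulation": "forbidden", **m.solver_log},
            )
        if deadline.exceeded():
            return _timeout_result(g, best, m, "sce_forbidden")


def _edits_between(g: Graph, h: Graph) -> EditSet:
    return EditSet(
        insertions=frozenset(h.edges - g.edges),
        deletions=frozenset(g.edges - h.edges),
    )


def _timeout_result(g, best, m, solver) -> SolveResult:
    x, _ = best
    cand = m.solution_graph(x)
    edits = _edits_between(g, cand)
    return SolveResult(
        edits=edits, objective=edits.size, partition=None, optimal=False,
        provenance={"solver": solver, "timeout": True, **m.solver_log},
    )


# -- SCE / ME: partition-variable formulations -----------------------------

def _p3_row(m: IlpModel, u: str, v: str, w: str, problem: str) -> tuple:
    """(6) for SCE / (7) for ME, for the triple with middle vertex v."""
    coefs = {
        m.evar(u, v): -1.0,
        m.evar(v, w): -1.0,
        m.evar(u, w): 1.0,
    }
    const = 2.0
    for z in ((u, w) if problem == "sce" else (u, v, w)):
        coefs[m.cvar(z)] = coefs.get(m.cvar(z), 0.0) - 1.0
        const += 1.0
    return coefs, 1.0 - const


def _violated_p3_rows(
    m: IlpModel, cand: Graph, core: frozenset, problem: str
) -> list[tuple]:
    rows = []
    for u, v, w in _induced_p3s(cand):
        if problem == "sce":
            bad = u in core and w in core
        else:
            bad = u in core and v in core and w in core
        if bad:
            rows.append(_p3_row(m, u, v, w, problem))
    return rows


def _solve_partition(g: Graph, problem: str, cfg: IlpConfig) -> SolveResult:
    solver = f"{problem}_partition"
    trivial = _trivial_result(g, problem, solver)
    if trivial:
        return trivial
    deadline = _Deadline(cfg.time_limit)
    m = IlpModel(g, core_vars=True)
    # (5): periphery is an independent set, for all vertex pairs
    for u, v in m.pairs:
        m.add_row({m.cvar(u): 1.0, m.cvar(v): 1.0, m.evar(u, v): -1.0}, 0.0)
    # P3 rows for triples inducing a P3 in the input graph
    for u, v, w in _induced_p3s(g):
        m.add_row(*_p3_row(m, u, v, w, problem))
    if cfg.obs1_fixing and problem == "sce":
        fix_variables_obs1(g, m)
    if cfg.warm_start:
        _warm_start_bound(g, problem, cfg, m)
    if cfg.cuts:
        kinds = ["P3", "C4", "P5"] if problem == "sce" else ["P3", "W4"]
        _lp_cut_phase(m, g, kinds, problem, cfg, deadline)
    best = None
    while True:
        x, obj, proven = m.solve(time_limit=deadline.remaining())
        cand = m.solution_graph(x)
        core = m.core_set(x)
        best = (x, obj)
        rows = _violated_p3_rows(m, cand, core, problem)
        if not rows:
            # the annotated characterization guarantees class membership now
            part = AnnotatedPartition(core=core, periphery=g.vertices - core)
            checker = (
                check_annotated_split_cluster if problem == "sce"
                else check_annotated_monopolar
            )
            ok, _viol = checker(cand, part)
            assert ok, "partition ILP produced an infeasible annotated graph"
            edits = _edits_between(g, cand)
            partition = _partition_from_annotated(cand, core, problem)
            return SolveResult(
                edits=edits, objective=edits.size, partition=partition,
                optimal=proven and not deadline.exceeded(),
                provenance={"solver": solver, "formulation": "partition",
                            **m.solver_log},
            )
        for row in rows:
            m.add_row(*row)
        m.solver_log["lazy_added"] += len(rows)
        if deadline.exceeded():
            return _timeout_result(g, best, m, solver)


def _partition_from_annotated(
    edited: Graph, core: frozenset, problem: str
) -> CorePeripheryPartition:
    if problem == "sce":
        # canonical per-component split partition (highest-degree core), not
        # the solver's arbitrary optimal core labeling
        parts = split_cluster_partition(edited)
        return CorePeripheryPartition(
            clusters=tuple((p.core, p.periphery) for p in parts),
            mode="per_cluster", graph=edited,
        )
    core_sub = induced_subgraph(edited, core)
    clusters = tuple(
        (comp, frozenset()) for comp in connected_components(core_sub)
    )
    return CorePeripheryPartition(
        clusters=clusters,
        shared_periphery=edited.vertices - core,
        mode="shared",
        graph=edited,
    )


def solve_sce_partition(g: Graph, cfg: IlpConfig = IlpConfig()) -> SolveResult:
    """Optimal split cluster editing via the partition-variable ILP."""
    return _solve_partition(g, "sce", cfg)


def solve_me_partition(g: Graph, cfg: IlpConfig = IlpConfig()) -> SolveResult:
    """Optimal monopolar editing via the partition-variable ILP."""
    return _solve_partition(g, "me", cfg)


# -- cluster editing -------------------------------------------------------

def solve_ce(g: Graph, cfg: IlpConfig = IlpConfig()) -> SolveResult:
    """Optimal cluster editing: edge variables with lazy P3 (conflict-triple)
    rows; the components of the result are cliques and size-1 clusters are
    interpreted as a shared periphery."""
    trivial = _trivial_result(g, "ce", "ce")
    if trivial:
        return trivial
    deadline = _Deadline(cfg.time_limit)
    m = IlpModel(g, core_vars=False)
    for u, v, w in _induced_p3s(g):
        m.add_row(
            {m.evar(u, v): -1.0, m.evar(v, w): -1.0, m.evar(u, w): 1.0}, -1.0
        )
    best = None
    while True:
        x, obj, proven = m.solve(time_limit=deadline.remaining())
        cand = m.solution_graph(x)
        best = (x, obj)
        p3s = _induced_p3s(cand)
        if not p3s:
            edits = _edits_between(g, cand)
            comps = connected_components(cand)
            clusters = tuple(
                (comp, frozenset()) for comp in comps if len(comp) > 1
            )
            singles = frozenset(
                v for comp in comps if len(comp) == 1 for v in comp
            )
            partition = CorePeripheryPartition(
                clusters=clusters, shared_periphery=singles,
                mode="shared", graph=cand,
            )
            return SolveResult(
                edits=edits, objective=edits.size, partition=partition,
                optimal=proven and not deadline.exceeded(),
                provenance={"solver": "ce", **m.solver_log},
            )
        for u, v, w in p3s:
            m.add_row(
                {m.evar(u, v): -1.0, m.evar(v, w): -1.0, m.evar(u, w): 1.0},
                -1.0,
            )
        m.solver_log["lazy_added"] += len(p3s)
        if deadline.exceeded():
            return _timeout_result(g, best, m, "ce")
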