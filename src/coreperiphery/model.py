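"""Model/Results front door for the editing problems.

The three fitting models share one pattern: construct a model from a graph
(or an edge-list file), call :meth:`fit`, and inspect the returned
:class:`EditingResults` - the minimum edit set, the core-periphery partition
it implies, optimality status, and a summary table.

>>> from coreperiphery import SplitClusterEditing
>>> from coreperiphery.synthetic import er_graph
>>> res = SplitClusterEditing(er_graph(12, 0.3, seed=1)).fit()
>>> res.objective  # number of edge modifications        # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional

from . import annealing, ilp, oracles
from .evaluation import ComplexSet, detect_complexes, filter_complexes, partition_stats
from .graph import Graph, apply_edits, read_edge_list
from .results import SolveResult

__all__ = [
    "SplitClusterEditing",
    "MonopolarEditing",
    "ClusterEditing",
    "EditingResults",
]


class _EditingModel:
    """Shared scaffolding: holds the input graph and dispatches fit methods."""

    problem: str = ""
    _methods: tuple = ()

    def __init__(self, graph: Graph):
        if not isinstance(graph, Graph):
            graph = Graph(graph.nodes, graph.edges)  # accept a networkx graph
        self.graph = graph

    @classmethod
    def from_edge_list(cls, path, dialect: str = "tsv") -> "_EditingModel":
        return cls(read_edge_list(path, dialect=dialect))

    def fit(self, method: str = "ilp", **kwargs) -> "EditingResults":
        """Solve the editing problem.

        Parameters
        ----------
        method : str
            One of the model's supported methods (see ``_methods``);
            ``"ilp"`` is exact, ``"anneal"`` is the simulated-annealing
            heuristic, ``"exact-dp"`` the subset-DP oracle (small graphs),
            ``"brute"`` edit-set enumeration (tiny graphs).
        kwargs :
            Forwarded to the solver configuration
            (:class:`coreperiphery.ilp.IlpConfig` or
            :class:`coreperiphery.annealing.AnnealConfig` fields).
        """
        if method not in self._methods:
            raise ValueError(
                f"{type(self).__name__} supports methods {self._methods}, "
                f"got {method!r}"
            )
        result = self._dispatch(method, **kwargs)
        return EditingResults(self, result, method)

    # subclasses override
    def _dispatch(self, method: str, **kwargs) -> SolveResult:
        raise NotImplementedError


def _dp_result(g: Graph, problem: str) -> SolveResult:
    value = oracles.exact_edit_value(g, problem)
    # value only; reuse the ILP route for a witnessing edit set
    solver = {
        "sce": ilp.solve_sce_partition,
        "me": ilp.solve_me_partition,
        "ce": ilp.solve_ce,
    }[problem]
    res = solver(g, ilp.IlpConfig(warm_start=False))
    assert res.objective == value
    return res


class SplitClusterEditing(_EditingModel):
    """Fit a graph to the disjoint core-periphery model: transform it into a
    graph whose every connected component is a split graph, with a minimum
    number of edge insertions and deletions."""

    problem = "sce"
    _methods = ("ilp", "anneal", "branch", "exact-dp", "brute")

    def _dispatch(self, method: str, formulation: str = "partition", **kw):
        g = self.graph
        if method == "ilp":
            cfg = ilp.IlpConfig(**kw)
            if formulation == "partition":
                return ilp.solve_sce_partition(g, cfg)
            if formulation == "forbidden":
                return ilp.solve_sce_forbidden(g, cfg)
            raise ValueError(f"unknown formulation {formulation!r}")
        if method == "anneal":
            return annealing.anneal_sce(g, annealing.AnnealConfig(**kw))
        if method == "branch":
            # iterative deepening on the 10^k search tree
            k = 0
            while True:
                edits = oracles.search_tree_sce(g, k)
                if edits is not None:
                    return SolveResult(
                        edits=edits, objective=edits.size, optimal=True,
                        provenance={"solver": "search_tree", "k": k},
                    )
                k += 1
        if method == "exact-dp":
            return _dp_result(g, "sce")
        return oracles.brute_force_edit(g, oracles.SPLIT_CLUSTER, **kw)


class MonopolarEditing(_EditingModel):
    """Fit a graph to the shared-periphery model: transform it into a
    monopolar graph (independent set + cluster graph) with a minimum number
    of edge modifications, and output the monopolar partition."""

    problem = "me"
    _methods = ("ilp", "anneal", "exact-dp", "brute")

    def _dispatch(self, method: str, **kw):
        g = self.graph
        if method == "ilp":
            return ilp.solve_me_partition(g, ilp.IlpConfig(**kw))
        if method == "anneal":
            return annealing.anneal_me(g, annealing.AnnealConfig(**kw))
        if method == "exact-dp":
            return _dp_result(g, "me")
        return oracles.brute_force_edit(g, oracles.MONOPOLAR, **kw)


class ClusterEditing(_EditingModel):
    """Classical cluster editing: transform the graph into disjoint cliques;
    size-1 clusters are interpreted as a shared periphery."""

    problem = "ce"
    _methods = ("ilp", "exact-dp", "brute")

    def _dispatch(self, method: str, **kw):
        g = self.graph
        if method == "ilp":
            return ilp.solve_ce(g, ilp.IlpConfig(**kw))
        if method == "exact-dp":
            return _dp_result(g, "ce")
        return oracles.brute_force_edit(g, oracles.CLUSTER, **kw)


class EditingResults:
    """Results of fitting an editing model: the edit set, the implied
    core-periphery partition, and evaluation helpers."""

    def __init__(self, model: _EditingModel, result: SolveResult, method: str):
        self.model = model
        self._result = result
        self.method = method

    # -- pass-through ------------------------------------------------------
    @property
    def objective(self) -> int:
        """The number of edge modifications k."""
        return self._result.objective

    @property
    def edits(self):
        return self._result.edits

    @property
    def partition(self):
        return self._result.partition

    @property
    def optimal(self) -> bool:
        return self._result.optimal

    @property
    def provenance(self) -> dict:
        return self._result.provenance

    @property
    def edited_graph(self) -> Graph:
        return apply_edits(self.model.graph, self.edits)

    # -- evaluation --------------------------------------------------------
    def stats(self) -> dict:
        return partition_stats(self.partition, self.edits)

    def evaluate_complexes(self, cx: ComplexSet, prefilter: bool = True) -> dict:
        """Complex-detection report against a gold standard; complexes are
        filtered against the input subnetwork first unless ``prefilter`` is
        False."""
        if prefilter:
            cx = filter_complexes(cx, self.model.graph)
        return detect_complexes(self.partition, cx)

    def summary(self) -> str:
        g = self.model.graph
        st = self.stats() if self.partition is not None else {}
        lines = [
            f"{type(self.model).__name__} results",
            "=" * 40,
            f"vertices:            {g.n}",
            f"edges:               {g.m}",
            f"method:              {self.method}"
            + (f" ({self.provenance.get('solver', '')})" if self.provenance else ""),
            f"edit count k:        {self.objective}"
            f"  (insert {len(self.edits.insertions)},"
            f" delete {len(self.edits.deletions)})",
            f"proven optimal:      {self.optimal}",
        ]
        if st:
            cm = st["core_mean"]
            pm = st["periphery_mean"]
            lines += [
                f"nontrivial clusters: {st['K']}",
                f"mean core size:      {cm if cm is None else round(cm, 2)}",
                f"mean periphery size: {pm if pm is None else round(pm, 2)}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<EditingResults {self.model.problem} k={self.objective} "
            f"optimal={self.optimal}>"
        )
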