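"""Independent ground-truth machinery used to validate every solver.

Three routes to exact optima, none sharing code with the ILP solvers:

* :func:`brute_force_edit` - iterative deepening over all edit sets of size
  k = 0, 1, 2, ...; exact by construction, feasible only for tiny graphs or
  small k.
* :func:`exact_edit_value` - exact optima for split cluster editing, monopolar
  editing and cluster editing via dynamic programming over vertex-subset
  bitmasks: every optimal solution is described by a partition of V into
  blocks (the components of the edited graph), so the optimum is
  m + min over partitions of sum of per-block costs, where a block costs
  splittance(block) - edges(block) for SCE and C(|block|,2) - 2*edges(block)
  for CE; monopolar editing additionally minimizes over the choice of the
  shared independent set.
* :func:`search_tree_sce` - the 10^k branching algorithm: find a forbidden
  subgraph, branch on toggling each of the at most ten vertex pairs inside it.

The module also enumerates graphs up to isomorphism (canonical form = minimum
adjacency bitstring over all vertex permutations, vectorized with numpy) and
derives minimal forbidden induced subgraphs of hereditary classes from it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional

import networkx as nx
import numpy as np

from .graph import Graph, EditSet, apply_edits, induced_subgraph
from .recognition import (
    CERTIFICATE_PATTERNS,
    is_monopolar_bruteforce,
    is_split,
    is_split_cluster,
    splittance,
)
from .results import SolveResult

__all__ = [
    "GraphClassPredicate",
    "SPLIT",
    "SPLIT_CLUSTER",
    "MONOPOLAR",
    "CLUSTER",
    "brute_force_edit",
    "exact_edit_value",
    "search_tree_sce",
    "nonisomorphic_graphs",
    "graph_from_bits",
    "enumerate_minimal_forbidden",
    "contains_induced",
    "pattern_graph",
]


@dataclass(frozen=True)
class GraphClassPredicate:
    """A named hereditary graph class with a total membership test."""

    name: str
    test: Callable[[Graph], bool]

    def __call__(self, g: Graph) -> bool:
        return self.test(g)


def _is_cluster(g: Graph) -> bool:
    for v in g.vertices:
        nb = sorted(g.neighbors(v))
        for u, w in itertools.combinations(nb, 2):
            if not g.has_edge(u, w):
                return False
    return True


SPLIT = GraphClassPredicate("split", lambda g: is_split(g)[0])
SPLIT_CLUSTER = GraphClassPredicate("split_cluster", lambda g: is_split_cluster(g)[0])
MONOPOLAR = GraphClassPredicate("monopolar", lambda g: is_monopolar_bruteforce(g)[0])
CLUSTER = GraphClassPredicate("cluster", _is_cluster)

PREDICATES = {p.name: p for p in (SPLIT, SPLIT_CLUSTER, MONOPOLAR, CLUSTER)}


# -- brute force by edit enumeration ---------------------------------------

def brute_force_edit(
    g: Graph,
    cls: GraphClassPredicate,
    k_max: Optional[int] = None,
    guard: int = 9,
) -> SolveResult:
    """Minimum-cardinality edit set reaching ``cls`` by iterative deepening.

    Enumerates all edit sets of size k = 0, 1, ... in lexicographic pair
    order and returns the first optimum found.  Exact by construction.
    Raises if the graph exceeds ``guard`` vertices, or if ``k_max`` is
    exhausted without success.
    """
    if g.n > guard:
        raise ValueError(f"graph has {g.n} > {guard} vertices")
    vs = g.sorted_vertices()
    all_pairs = [frozenset(p) for p in itertools.combinations(vs, 2)]
    limit = k_max if k_max is not None else len(all_pairs)
    for k in range(limit + 1):
        for combo in itertools.combinations(all_pairs, k):
            ins = frozenset(p for p in combo if p not in g.edges)
            dels = frozenset(p for p in combo if p in g.edges)
            es = EditSet(ins, dels)
            if cls(apply_edits(g, es)):
                return SolveResult(
                    edits=es,
                    objective=k,
                    optimal=True,
                    provenance={"solver": "brute_force", "class": cls.name},
                )
    raise ValueError(f"no edit set of size <= {limit} reaches class {cls.name}")


# -- exact values by subset dynamic programming ----------------------------

def _bit_tables(g: Graph) -> tuple[list[str], list[int], list[int]]:
    """Adjacency bitmasks, edges-within table, and splittance table over all
    2^n vertex subsets."""
    vs = g.sorted_vertices()
    n = len(vs)
    idx = {v: i for i, v in enumerate(vs)}
    adj = [0] * n
    for e in g.edges:
        u, v = tuple(e)
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    size = 1 << n
    ew = [0] * size  # edges within subset
    for mask in range(1, size):
        low = (mask & -mask).bit_length() - 1
        rest = mask ^ (1 << low)
        ew[mask] = ew[rest] + bin(adj[low] & rest).count("1")
    spl = [0] * size  # splittance of induced subgraph
    for mask in range(1, size):
        degs = [
            bin(adj[i] & mask).count("1") for i in range(n) if mask >> i & 1
        ]
        d = sorted(degs, reverse=True)
        k = 0
        for i, di in enumerate(d, start=1):
            if di >= i - 1:
                k = i
        spl[mask] = (k * (k - 1) - sum(d[:k]) + sum(d[k:])) // 2
    return vs, ew, spl


def _partition_dp(n: int, block_cost: list[int]) -> list[int]:
    """f[mask] = min over partitions of ``mask`` into blocks of the summed
    block costs; each block must contain the lowest set bit of its remainder."""
    size = 1 << n
    f = [0] * size
    for mask in range(1, size):
        low = 1 << ((mask & -mask).bit_length() - 1)
        rest = mask ^ low
        best = None
        sub = rest
        while True:  # iterate over all blocks containing `low`
            block = sub | low
            cand = block_cost[block] + f[mask ^ block]
            if best is None or cand < best:
                best = cand
            if sub == 0:
                break
            sub = (sub - 1) & rest
        f[mask] = best
    return f


def exact_edit_value(g: Graph, problem: str, guard: int = 16) -> int:
    """Exact optimum of ``sce``, ``me``, or ``ce`` on ``g`` by subset DP."""
    if g.n > guard:
        raise ValueError(f"graph has {g.n} > {guard} vertices")
    if g.n == 0:
        return 0
    vs, ew, spl = _bit_tables(g)
    n = len(vs)
    full = (1 << n) - 1
    m = g.m
    if problem == "sce":
        cost = [spl[b] - ew[b] for b in range(1 << n)]
        return m + _partition_dp(n, cost)[full]
    # CE-style block cost: missing pairs minus twice the internal edges
    cost = [0] * (1 << n)
    for b in range(1, 1 << n):
        s = bin(b).count("1")
        cost[b] = s * (s - 1) // 2 - 2 * ew[b]
    h = _partition_dp(n, cost)
    if problem == "ce":
        return m + h[full]
    if problem == "me":
        best = None
        for I in range(1 << n):
            comp = full ^ I
            cand = ew[I] + ew[comp] + h[comp]
            if best is None or cand < best:
                best = cand
        return best
    raise ValueError(f"unknown problem {problem!r}")


# -- the 10^k search tree for split cluster editing ------------------------

def search_tree_sce(g: Graph, k_budget: int) -> Optional[EditSet]:
    """Depth-bounded branching: destroy a forbidden subgraph by toggling one
    of the at most ten vertex pairs inside it, recursing with budget - 1.

    Returns an edit set of size <= ``k_budget`` turning ``g`` into a split
    cluster graph, or None if none exists.  Pairs already toggled on the
    current branch path are never toggled back.
    """

    def rec(h: Graph, budget: int, blocked: frozenset) -> Optional[frozenset]:
        ok, cert = is_split_cluster(h)
        if ok:
            return frozenset()
        if budget == 0:
            return None
        for u, v in itertools.combinations(sorted(cert.vertices), 2):
            pair = frozenset((u, v))
            if pair in blocked:
                continue
            if pair in h.edges:
                h2 = Graph(h.vertices, h.edges - {pair})
            else:
                h2 = Graph(h.vertices, h.edges | {pair})
            sub = rec(h2, budget - 1, blocked | {pair})
            if sub is not None:
                return sub | {pair}
        return None

    toggled = rec(g, k_budget, frozenset())
    if toggled is None:
        return None
    return EditSet(
        insertions=frozenset(p for p in toggled if p not in g.edges),
        deletions=frozenset(p for p in toggled if p in g.edges),
    )


# -- enumeration of graphs up to isomorphism -------------------------------

def _pairs_colex(n: int) -> list[tuple[int, int]]:
    """Vertex pairs in colexicographic order, so that the pairs touching the
    last vertex occupy the highest indices (needed by the one-vertex
    extension in :func:`nonisomorphic_graphs`)."""
    return [(i, j) for j in range(n) for i in range(j)]


def _pair_index(n: int) -> dict[tuple[int, int], int]:
    return {p: t for t, p in enumerate(_pairs_colex(n))}


@lru_cache(maxsize=None)
def _perm_maps(n: int) -> np.ndarray:
    """For each permutation of n vertices, the induced permutation of pair
    indices; shape (n!, n(n-1)/2)."""
    idx = _pair_index(n)
    maps = []
    for sigma in itertools.permutations(range(n)):
        maps.append(
            [idx[tuple(sorted((sigma[i], sigma[j])))] for (i, j) in idx]
        )
    return np.asarray(maps, dtype=np.int64)


def _canonicalize(n: int, ints: np.ndarray) -> np.ndarray:
    """Canonical form of each adjacency bitmask: the minimum over all vertex
    permutations of the permuted bitmask."""
    npairs = n * (n - 1) // 2
    if npairs == 0:
        return np.zeros_like(ints)
    bits = ((ints[:, None] >> np.arange(npairs)) & 1).astype(np.int64)
    weights = (1 << np.arange(npairs)).astype(np.int64)
    best = np.full(len(ints), np.iinfo(np.int64).max)
    for pm in _perm_maps(n):
        np.minimum(best, bits[:, pm] @ weights, out=best)
    return best


@lru_cache(maxsize=None)
def nonisomorphic_graphs(n: int) -> tuple[int, ...]:
    """All graphs on exactly ``n`` labeled-canonically vertices, one adjacency
    bitmask per isomorphism class (pairs in lexicographic order)."""
    if n > 7:
        raise ValueError("enumeration is guarded at n <= 7")
    if n == 0:
        return (0,)
    if n == 1:
        return (0,)
    # extend every (n-1)-vertex class by one vertex with every neighborhood
    prev = nonisomorphic_graphs(n - 1)
    old_pairs = (n - 1) * (n - 2) // 2
    cands = []
    for bits in prev:
        for nb in range(1 << (n - 1)):
            cands.append(bits | (nb << old_pairs))
    canon = _canonicalize(n, np.asarray(cands, dtype=np.int64))
    return tuple(sorted(set(int(x) for x in canon)))


def graph_from_bits(n: int, bits: int) -> Graph:
    labels = [f"v{i}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for t, (i, j) in enumerate(_pairs_colex(n))
        if bits >> t & 1
    ]
    return Graph(labels, edges)


def pattern_graph(kind: str) -> Graph:
    """Reference graph of a certificate kind (P3, C4, ..., W4)."""
    pattern = CERTIFICATE_PATTERNS[kind]
    size = max(max(p) for p in pattern) + 1
    return Graph(
        [f"v{i}" for i in range(size)],
        [(f"v{i}", f"v{j}") for i, j in pattern],
    )


def contains_induced(g: Graph, kind: str) -> bool:
    """Brute-force test for an induced subgraph isomorphic to ``kind``."""
    ref = pattern_graph(kind)
    size = ref.n
    ref_nx = ref.to_networkx()
    ref_degs = sorted(d for _, d in ref_nx.degree())
    for combo in itertools.combinations(g.sorted_vertices(), size):
        sub = induced_subgraph(g, combo)
        if sub.m != ref.m:
            continue
        if sorted(sub.degree_sequence()) != ref_degs:
            continue
        if nx.is_isomorphic(sub.to_networkx(), ref_nx):
            return True
    return False


def enumerate_minimal_forbidden(
    cls: GraphClassPredicate, n_max: int, guard: int = 7
) -> list[Graph]:
    """All minimal forbidden induced subgraphs of ``cls`` on <= ``n_max``
    vertices, up to isomorphism.

    A graph is minimal forbidden if it is not in the class but every proper
    induced subgraph is; for a hereditary class it suffices to check the
    (n-1)-vertex induced subgraphs.
    """
    if n_max > guard:
        raise ValueError(f"n_max={n_max} exceeds guard {guard}")
    out = []
    for n in range(1, n_max + 1):
        for bits in nonisomorphic_graphs(n):
            g = graph_from_bits(n, bits)
            if cls(g):
                continue
            vs = g.sorted_vertices()
            if all(
                cls(induced_subgraph(g, set(vs) - {v})) for v in vs
            ):
                out.append(g)
    return out
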