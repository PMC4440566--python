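"""Certificate-producing recognition of split, split cluster, and monopolar graphs.

A *split graph* partitions into a clique (core) and an independent set
(periphery); it is exactly a (2K2, C4, C5)-free graph, and membership is
decided by the degree sequence alone through the Hammer-Simeone splittance.
A *split cluster graph* has a split graph as every connected component and is
exactly the (C4, C5, P5, necktie, bowtie)-free graphs: a 2K2 found inside a
connected component can always be relocated next to a common attachment
vertex, and the five vertices then induce a P5, a necktie, or a bowtie
depending on how many of the two optional triangle edges are present.
A *monopolar graph* partitions into an independent set and a cluster graph;
recognition is NP-hard in general and is done here by exhaustive branching
on induced P3s (exact, guarded by an input-size bound).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .graph import Graph, connected_components, induced_subgraph

__all__ = [
    "ForbiddenCertificate",
    "AnnotatedPartition",
    "CERTIFICATE_PATTERNS",
    "splittance",
    "is_graphical",
    "is_split",
    "split_partition",
    "is_split_cluster",
    "split_cluster_partition",
    "localize_2K2",
    "check_annotated_split_cluster",
    "check_annotated_monopolar",
    "is_monopolar_bruteforce",
]

# Edge patterns on tuple positions defining each certificate kind.
CERTIFICATE_PATTERNS: dict[str, frozenset] = {
    "P3": frozenset({(0, 1), (1, 2)}),
    "2K2": frozenset({(0, 1), (2, 3)}),
    "C4": frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}),
    "C5": frozenset({(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)}),
    "P5": frozenset({(0, 1), (1, 2), (2, 3), (3, 4)}),
    # (a, b, v, c, d): triangle a-b-v plus path v-c-d
    "necktie": frozenset({(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)}),
    # (a, b, v, c, d): triangles a-b-v and c-d-v sharing v
    "bowtie": frozenset({(0, 1), (0, 2), (1, 2), (2, 3), (2, 4), (3, 4)}),
    # (hub, r1, r2, r3, r4): 4-cycle r1-r2-r3-r4 plus hub adjacent to all
    "W4": frozenset(
        {(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (2, 3), (3, 4), (1, 4)}
    ),
}


@dataclass(frozen=True)
class ForbiddenCertificate:
    """A typed witness that a graph is outside a hereditary class.

    ``vertices`` is an ordered tuple whose induced subgraph realizes ``kind``
    with the positional edge pattern of :data:`CERTIFICATE_PATTERNS`.
    """

    kind: str
    vertices: tuple

    def __post_init__(self):
        if self.kind not in CERTIFICATE_PATTERNS:
            raise ValueError(f"unknown certificate kind {self.kind!r}")
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("certificate vertices must be distinct")

    def verify(self, g: Graph) -> bool:
        """True iff the induced subgraph matches the kind's edge pattern."""
        vs = self.vertices
        pattern = CERTIFICATE_PATTERNS[self.kind]
        for i, j in itertools.combinations(range(len(vs)), 2):
            want = (i, j) in pattern or (j, i) in pattern
            if g.has_edge(vs[i], vs[j]) != want:
                return False
        return True


@dataclass(frozen=True)
class AnnotatedPartition:
    """A two-partition of the vertex set into core ``C`` and periphery ``I``."""

    core: frozenset
    periphery: frozenset

    def __post_init__(self):
        object.__setattr__(self, "core", frozenset(self.core))
        object.__setattr__(self, "periphery", frozenset(self.periphery))
        if self.core & self.periphery:
            raise ValueError("core and periphery must be disjoint")

    def covers(self, g: Graph) -> bool:
        return self.core | self.periphery == g.vertices


# -- splittance ------------------------------------------------------------

def is_graphical(degrees: Iterable[int]) -> bool:
    """Erdos-Gallai test for a degree sequence being realizable."""
    d = sorted(degrees, reverse=True)
    n = len(d)
    if any(x < 0 or x > n - 1 for x in d):
        return False
    if sum(d) % 2:
        return False
    for k in range(1, n + 1):
        lhs = sum(d[:k])
        rhs = k * (k - 1) + sum(min(x, k) for x in d[k:])
        if lhs > rhs:
            return False
    return True


def splittance(degrees: Iterable[int]) -> int:
    """Minimum number of edge edits turning a graph with this degree sequence
    into a split graph (a function of the degree sequence alone).

    With degrees sorted descending d1 >= ... >= dn and k the largest index with
    d_k >= k - 1, the value is (k(k-1) - sum_{i<=k} d_i + sum_{i>k} d_i) / 2.
    """
    d = sorted(degrees, reverse=True)
    if not is_graphical(d):
        raise ValueError(f"degree sequence {d} is not graphical")
    k = 0
    for i, di in enumerate(d, start=1):
        if di >= i - 1:
            k = i
    twice = k * (k - 1) - sum(d[:k]) + sum(d[k:])
    assert twice % 2 == 0 and twice >= 0
    return twice // 2


def split_partition(g: Graph) -> tuple[AnnotatedPartition, int]:
    """Hammer-Simeone split partition: the k highest-degree vertices as core.

    Returns the partition together with its edit cost
    (missing core pairs + periphery-periphery edges), which equals the
    splittance of g's degree sequence.  Ties are broken lexicographically.
    """
    vs = sorted(g.vertices, key=lambda v: (-g.degree(v), v))
    d = [g.degree(v) for v in vs]
    k = 0
    for i, di in enumerate(d, start=1):
        if di >= i - 1:
            k = i
    core = set(vs[:k])
    peri = set(vs[k:])
    missing = k * (k - 1) // 2 - sum(1 for e in g.edges if e <= core)
    extra = sum(1 for e in g.edges if e <= peri)
    if missing + extra == 0:
        # degree-one vertices whose neighbor has degree > 1 are periphery
        # vertices in some optimal solution; demote them for a canonical
        # witness (their sole neighbor is necessarily a core vertex)
        for u in sorted(core):
            if g.degree(u) == 1:
                (v,) = g.neighbors(u)
                if g.degree(v) > 1:
                    core.discard(u)
                    peri.add(u)
    return AnnotatedPartition(frozenset(core), frozenset(peri)), missing + extra


# -- certificate searches --------------------------------------------------

def _find_2K2(g: Graph) -> Optional[tuple]:
    """An induced 2K2 as ((a,b),(c,d)), or None. Deterministic, lexicographic scan."""
    es = g.sorted_edges()
    for i, (a, b) in enumerate(es):
        for c, d in es[i + 1:]:
            if len({a, b, c, d}) != 4:
                continue
            if (
                not g.has_edge(a, c) and not g.has_edge(a, d)
                and not g.has_edge(b, c) and not g.has_edge(b, d)
            ):
                return ((a, b), (c, d))
    return None


def _find_C4(g: Graph) -> Optional[tuple]:
    """An induced C4 as an ordered cycle (u, x, v, y), or None."""
    vs = g.sorted_vertices()
    for i, u in enumerate(vs):
        for v in vs[i + 1:]:
            if g.has_edge(u, v):
                continue
            common = sorted(g.neighbors(u) & g.neighbors(v))
            for x, y in itertools.combinations(common, 2):
                if not g.has_edge(x, y):
                    return (u, x, v, y)
    return None


def _find_C5(g: Graph) -> Optional[tuple]:
    """An induced C5 as an ordered cycle, or None."""
    for a in g.sorted_vertices():
        for b in sorted(g.neighbors(a)):
            for c in sorted(g.neighbors(b)):
                if c == a or g.has_edge(a, c):
                    continue
                for d in sorted(g.neighbors(c)):
                    if d in (a, b) or g.has_edge(a, d) or g.has_edge(b, d):
                        continue
                    for e_ in sorted(g.neighbors(d) & g.neighbors(a)):
                        if e_ in (b, c):
                            continue
                        if not g.has_edge(e_, b) and not g.has_edge(e_, c):
                            return (a, b, c, d, e_)
    return None


def is_split(
    g: Graph,
) -> tuple[bool, Optional[ForbiddenCertificate], Optional[AnnotatedPartition]]:
    """Decide split-graph membership; on success return a clique/independent-set
    partition, on failure a 2K2, C4, or C5 certificate."""
    if g.n == 0:
        return True, None, AnnotatedPartition(frozenset(), frozenset())
    part, cost = split_partition(g)
    if cost == 0:
        return True, None, part
    for finder, kind in ((_find_2K2, "2K2"), (_find_C4, "C4"), (_find_C5, "C5")):
        found = finder(g)
        if found is not None:
            vs = found[0] + found[1] if kind == "2K2" else found
            cert = ForbiddenCertificate(kind, tuple(vs))
            assert cert.verify(g)
            return False, cert, None
    raise AssertionError("positive splittance but no forbidden subgraph found")


# -- split cluster graphs --------------------------------------------------

def localize_2K2(g: Graph, pair1, pair2) -> tuple[tuple, tuple, str]:
    """Relocate an induced 2K2 within its connected component next to a common
    attachment vertex.

    Returns ``((a, b), (c, d), v)`` where {a,b},{c,d} induce a 2K2 and the
    vertex ``v`` outside it is adjacent to at least one endpoint of each pair.
    Follows the shortest-path case analysis (path on 3, 4, or >=5 vertices).
    """
    x1, x2 = pair1
    y1, y2 = pair2
    cert = ForbiddenCertificate("2K2", (x1, x2, y1, y2))
    if not cert.verify(g):
        raise ValueError("input pairs do not induce a 2K2")
    gnx = g.to_networkx()
    best = None
    for xi in (x1, x2):
        for yj in (y1, y2):
            try:
                p = nx.shortest_path(gnx, xi, yj)
            except nx.NetworkXNoPath as exc:
                raise ValueError("2K2 endpoints lie in different components") from exc
            if best is None or len(p) < len(best):
                best = p
    path = best
    k = len(path)
    assert k > 2, "2K2 endpoints cannot be adjacent"
    if k == 3:
        v = path[1]
        rx = x2 if path[0] == x1 else x1
        ry = y2 if path[2] == y1 else y1
        return ((path[0], rx), (path[2], ry), v)
    if k == 4:
        # {partner, path[0]} and {path[2], path[3]} form a 2K2; path[1] attaches.
        px = x2 if path[0] == x1 else x1
        return ((path[0], px), (path[2], path[3]), path[1])
    # k >= 5: the first five path vertices induce a P5; its outer pairs are a 2K2.
    p1, p2, p3, p4, p5 = path[:5]
    return ((p1, p2), (p4, p5), p3)


def _classify_localized(g: Graph, pair1, pair2, v) -> ForbiddenCertificate:
    """Classify the 5 vertices of a localized 2K2 plus attachment vertex as a
    P5, necktie, or bowtie certificate (0 / 1 / 2 extra edges to ``v``)."""
    a, b = pair1
    c, d = pair2
    # orient each pair so that v is adjacent to the first element
    if not g.has_edge(v, a):
        a, b = b, a
    if not g.has_edge(v, c):
        c, d = d, c
    left = g.has_edge(v, b)
    right = g.has_edge(v, d)
    if not left and not right:
        cert = ForbiddenCertificate("P5", (b, a, v, c, d))
    elif left and right:
        cert = ForbiddenCertificate("bowtie", (a, b, v, c, d))
    elif left:
        cert = ForbiddenCertificate("necktie", (a, b, v, c, d))
    else:
        cert = ForbiddenCertificate("necktie", (c, d, v, a, b))
    assert cert.verify(g), (cert, g.sorted_edges())
    return cert


def is_split_cluster(g: Graph) -> tuple[bool, Optional[ForbiddenCertificate]]:
    """True iff every connected component of ``g`` is a split graph.

    On failure returns a C4, C5, P5, necktie, or bowtie certificate; a 2K2
    discovered inside a component is localized and classified.
    """
    for comp in connected_components(g):
        sub = induced_subgraph(g, comp)
        ok, cert, _ = is_split(sub)
        if ok:
            continue
        if cert.kind in ("C4", "C5"):
            return False, cert
        pair1 = (cert.vertices[0], cert.vertices[1])
        pair2 = (cert.vertices[2], cert.vertices[3])
        lp1, lp2, v = localize_2K2(sub, pair1, pair2)
        return False, _classify_localized(sub, lp1, lp2, v)
    return True, None


def split_cluster_partition(g: Graph) -> Optional[list[AnnotatedPartition]]:
    """Per-component core/periphery partitions of a split cluster graph,
    ordered like :func:`connected_components`; None if g is not one."""
    parts = []
    for comp in connected_components(g):
        sub = induced_subgraph(g, comp)
        part, cost = split_partition(sub)
        if cost != 0:
            return None
        parts.append(part)
    return parts


# -- annotated checks (fixed core/periphery assignment) --------------------

def _find_p3_with(
    g: Graph, middle_ok, endpoint_ok
) -> Optional[tuple]:
    """An induced P3 (u, v, w) with endpoint_ok(u), endpoint_ok(w) and
    middle_ok(v), or None."""
    for v in g.sorted_vertices():
        if not middle_ok(v):
            continue
        nb = sorted(u for u in g.neighbors(v) if endpoint_ok(u))
        for u, w in itertools.combinations(nb, 2):
            if not g.has_edge(u, w):
                return (u, v, w)
    return None


def check_annotated_split_cluster(
    g: Graph, p: AnnotatedPartition
) -> tuple[bool, Optional[object]]:
    """Is ``g`` a split cluster graph with cores ``p.core`` and periphery
    ``p.periphery``?  A violation is an I-I edge or an induced P3 with both
    endpoints in C (the middle vertex may lie anywhere)."""
    if not p.covers(g):
        raise ValueError("partition does not cover the vertex set")
    I, C = p.periphery, p.core
    for e in g.sorted_edges():
        if e[0] in I and e[1] in I:
            return False, ("edge", e)
    p3 = _find_p3_with(g, lambda v: True, lambda u: u in C)
    if p3 is not None:
        return False, ("P3", p3)
    return True, None


def check_annotated_monopolar(
    g: Graph, p: AnnotatedPartition
) -> tuple[bool, Optional[object]]:
    """Is ``g`` monopolar with independent set ``p.periphery`` and cluster
    graph on ``p.core``?  A violation is an I-I edge or an induced P3 whose
    three vertices all lie in C."""
    if not p.covers(g):
        raise ValueError("partition does not cover the vertex set")
    I, C = p.periphery, p.core
    for e in g.sorted_edges():
        if e[0] in I and e[1] in I:
            return False, ("edge", e)
    p3 = _find_p3_with(g, lambda v: v in C, lambda u: u in C)
    if p3 is not None:
        return False, ("P3", p3)
    return True, None


# -- monopolar recognition (exact, exponential) ----------------------------

def is_monopolar_bruteforce(
    g: Graph, max_n: int = 20
) -> tuple[bool, Optional[AnnotatedPartition]]:
    """Exact monopolar recognition by branching on induced P3s.

    While the candidate core contains an induced P3, one of its three vertices
    must move to the independent set; a vertex may move only if it has no
    neighbor already there.  Exhausts a search tree of branching factor 3 and
    is exact; guarded by ``max_n`` since the problem is NP-hard.
    """
    if g.n > max_n:
        raise ValueError(
            f"graph has {g.n} > {max_n} vertices; use the ILP or annealing route"
        )

    adj = {v: g.neighbors(v) for v in g.vertices}

    def branch(I: set) -> Optional[frozenset]:
        C = g.vertices - I
        sub = induced_subgraph(g, C)
        p3 = _find_p3_with(sub, lambda v: True, lambda u: True)
        if p3 is None:
            return frozenset(I)
        for v in p3:
            if adj[v] & I:
                continue
            I.add(v)
            res = branch(I)
            if res is not None:
                return res
            I.remove(v)
        return None

    result = branch(set())
    if result is None:
        return False, None
    part = AnnotatedPartition(core=g.vertices - result, periphery=result)
    ok, _ = check_annotated_monopolar(g, part)
    assert ok
    return True, part
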