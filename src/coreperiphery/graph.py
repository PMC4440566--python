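"""Immutable undirected simple graphs with string vertex labels, plus edit sets.

This is the data model shared by every solver in the package: a finite simple
graph ``G = (V, E)`` whose vertices are opaque string labels, and an
:class:`EditSet` of edge insertions/deletions whose cardinality is the
optimization objective *k* of the editing problems.  Graphs are immutable from
the caller's point of view; applying edits produces a new graph.

Standard graph algorithms (connected components, shortest paths, diameter)
are delegated to :mod:`networkx`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Graph",
    "EditSet",
    "edge",
    "read_edge_list",
    "write_edge_list",
    "connected_components",
    "induced_subgraph",
    "apply_edits",
    "component_diameter",
]


def edge(u: str, v: str) -> frozenset:
    """Canonical unordered representation of an edge {u, v}."""
    if u == v:
        raise ValueError(f"self-loop {u!r} is not a valid edge of a simple graph")
    return frozenset((u, v))


class Graph:
    """A finite undirected simple graph over string vertex labels.

    Parameters
    ----------
    vertices : iterable of str
        Vertex labels (isolated vertices are first-class).
    edges : iterable of pairs
        Unordered pairs of labels; endpoints are added to the vertex set.
        Self-loops are rejected; duplicate / reversed pairs collapse.
    """

    __slots__ = ("_vertices", "_edges", "_adj", "_hash")

    def __init__(self, vertices: Iterable[str] = (), edges: Iterable = ()):
        vset = {str(v) for v in vertices}
        eset = set()
        adj: dict[str, set] = {v: set() for v in vset}
        for pair in edges:
            u, v = pair
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop {u!r} is not allowed")
            for w in (u, v):
                if w not in adj:
                    adj[w] = set()
                    vset.add(w)
            eset.add(frozenset((u, v)))
            adj[u].add(v)
            adj[v].add(u)
        self._vertices = frozenset(vset)
        self._edges = frozenset(eset)
        self._adj = {v: frozenset(s) for v, s in adj.items()}
        self._hash = None

    # -- basic accessors ---------------------------------------------------
    @property
    def vertices(self) -> frozenset:
        return self._vertices

    @property
    def edges(self) -> frozenset:
        return self._edges

    @property
    def n(self) -> int:
        return len(self._vertices)

    @property
    def m(self) -> int:
        return len(self._edges)

    def neighbors(self, u: str) -> frozenset:
        return self._adj[u]

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self._edges

    def has_vertex(self, u: str) -> bool:
        return u in self._vertices

    def degree_sequence(self) -> list[int]:
        """Degrees sorted descending."""
        return sorted((len(s) for s in self._adj.values()), reverse=True)

    def sorted_vertices(self) -> list[str]:
        return sorted(self._vertices)

    def sorted_edges(self) -> list[tuple]:
        return sorted(tuple(sorted(e)) for e in self._edges)

    def non_edges(self) -> Iterator[frozenset]:
        """All unordered vertex pairs that are not edges."""
        vs = self.sorted_vertices()
        for i, u in enumerate(vs):
            for v in vs[i + 1:]:
                if v not in self._adj[u]:
                    yield frozenset((u, v))

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._vertices)
        g.add_edges_from(tuple(e) for e in self._edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls(g.nodes, g.edges)

    # -- dunder ------------------------------------------------------------
    def __contains__(self, u: str) -> bool:
        return u in self._vertices

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._vertices == other._vertices and self._edges == other._edges

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self._vertices, self._edges))
        return self._hash

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class EditSet:
    """A set of edge insertions and deletions; ``size`` is the parameter *k*.

    Invariants: insertions and deletions are disjoint sets of unordered pairs;
    with respect to the graph being edited, insertions are non-edges and
    deletions are edges (checked by :func:`apply_edits`).
    """

    insertions: frozenset = field(default_factory=frozenset)
    deletions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        ins = frozenset(frozenset(p) for p in self.insertions)
        dels = frozenset(frozenset(p) for p in self.deletions)
        if any(len(p) != 2 for p in ins | dels):
            raise ValueError("edits must be unordered pairs of distinct vertices")
        if ins & dels:
            raise ValueError("insertions and deletions must be disjoint")
        object.__setattr__(self, "insertions", ins)
        object.__setattr__(self, "deletions", dels)

    @property
    def size(self) -> int:
        return len(self.insertions) + len(self.deletions)

    @property
    def pairs(self) -> frozenset:
        return self.insertions | self.deletions

    def inverse(self) -> "EditSet":
        """The edit set undoing this one (insertions and deletions swap)."""
        return EditSet(insertions=self.deletions, deletions=self.insertions)

    def __len__(self) -> int:
        return self.size


# -- I/O -------------------------------------------------------------------

def read_edge_list(path, dialect: str = "tsv") -> Graph:
    """Read a graph from a whitespace-separated edge list or a SIF file.

    ``tsv`` lines are ``u v`` (extra fields ignored); ``sif`` lines are
    ``u relation v [v2 ...]`` with the relation ignored.  Lines starting with
    ``#`` are comments; a single-field line declares an isolated vertex.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    vertices: set[str] = set()
    edges: set[frozenset] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                vertices.add(fields[0])
                continue
            if dialect == "tsv":
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line needs 'source relation target', "
                        f"got {len(fields)} fields"
                    )
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                if u == v:
                    raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
                vertices.update((u, v))
                edges.add(frozenset((u, v)))
    return Graph(vertices, edges)


def write_edge_list(g: Graph, path) -> None:
    """Write a 2-column TSV edge list; isolated vertices as single-field lines."""
    with open(path, "w") as fh:
        for u, v in g.sorted_edges():
            fh.write(f"{u}\t{v}\n")
        for v in g.sorted_vertices():
            if g.degree(v) == 0:
                fh.write(f"{v}\n")


# -- elementary operations -------------------------------------------------

def connected_components(g: Graph) -> list[frozenset]:
    """Maximal connected vertex sets, ordered by their smallest member."""
    comps = [frozenset(c) for c in nx.connected_components(g.to_networkx())]
    return sorted(comps, key=lambda c: min(c))


def induced_subgraph(g: Graph, s: Iterable[str]) -> Graph:
    """The subgraph of ``g`` induced by vertex set ``s``."""
    s = set(s)
    unknown = s - set(g.vertices)
    if unknown:
        raise ValueError(f"unknown vertex labels: {sorted(unknown)}")
    edges = [e for e in g.edges if e <= s]
    return Graph(s, edges)


def apply_edits(g: Graph, e: EditSet) -> Graph:
    """Apply an edit set, returning a new graph.

    Involutive via :meth:`EditSet.inverse`: applying the inverse edit set to
    the result restores the input.  Inserting an existing edge or deleting an
    absent one is an error.
    """
    bad_ins = e.insertions & g.edges
    if bad_ins:
        raise ValueError(f"insertion of existing edge(s): {sorted(map(sorted, bad_ins))}")
    if not e.deletions <= g.edges:
        bad = e.deletions - g.edges
        raise ValueError(f"deletion of absent edge(s): {sorted(map(sorted, bad))}")
    stray = {v for p in e.pairs for v in p} - set(g.vertices)
    if stray:
        raise ValueError(f"edits touch unknown vertices: {sorted(stray)}")
    return Graph(g.vertices, (g.edges | e.insertions) - e.deletions)


def component_diameter(g: Graph, comp: Iterable[str]) -> int:
    """Maximum shortest-path length between vertices of a connected component."""
    sub = induced_subgraph(g, comp).to_networkx()
    if sub.number_of_nodes() == 0:
        raise ValueError("empty component has no diameter")
    if not nx.is_connected(sub):
        raise ValueError("component is not connected in g")
    return nx.diameter(sub)
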