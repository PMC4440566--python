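"""Shared result containers: core-periphery partitions and solver results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .graph import EditSet, Graph

__all__ = ["CorePeripheryPartition", "SolveResult"]


@dataclass(frozen=True)
class CorePeripheryPartition:
    """Cluster assignment plus core/periphery roles.

    ``per_cluster`` mode (split cluster editing): each cluster owns a disjoint
    periphery; cluster vertex sets partition V.  ``shared`` mode (monopolar /
    cluster editing): clusters are cores only and ``shared_periphery`` is one
    independent set; a cluster's *effective* periphery is the neighborhood
    N(core) of its core, taken in ``graph`` (normally the edited graph).
    """

    clusters: tuple
    shared_periphery: frozenset = frozenset()
    mode: str = "per_cluster"
    graph: Optional[Graph] = None

    def __post_init__(self):
        if self.mode not in ("per_cluster", "shared"):
            raise ValueError(f"unknown mode {self.mode!r}")
        norm = tuple(
            (frozenset(core), frozenset(peri)) for core, peri in self.clusters
        )
        object.__setattr__(self, "clusters", norm)
        object.__setattr__(self, "shared_periphery", frozenset(self.shared_periphery))
        cores = [c for c, _ in norm]
        seen: set = set()
        for c in cores:
            if c & seen:
                raise ValueError("cores must be pairwise disjoint")
            seen |= c

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def effective_periphery(self, i: int, graph: Optional[Graph] = None) -> frozenset:
        """The periphery attributed to cluster ``i``.

        In shared mode this is N(core) in the given graph (default: the
        partition's own ``graph``); in per-cluster mode it is the cluster's
        stored periphery.
        """
        core, peri = self.clusters[i]
        if self.mode == "per_cluster":
            return peri
        g = graph if graph is not None else self.graph
        if g is None:
            raise ValueError("shared mode needs a graph to compute N(core)")
        nb: set = set()
        for u in core:
            nb |= g.neighbors(u)
        return frozenset(nb - core)

    def cluster_vertices(self, i: int, graph: Optional[Graph] = None) -> frozenset:
        core, _ = self.clusters[i]
        return core | self.effective_periphery(i, graph)

    def vertex_rows(self) -> list[tuple[str, str, str]]:
        """(vertex, cluster-id, role) rows for the 3-column TSV output."""
        rows = []
        for i, (core, peri) in enumerate(self.clusters):
            cid = str(i)
            rows.extend((v, cid, "core") for v in sorted(core))
            rows.extend((v, cid, "periphery") for v in sorted(peri))
        rows.extend((v, "-", "periphery") for v in sorted(self.shared_periphery))
        return rows

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("vertex\tcluster\trole\n")
            for row in self.vertex_rows():
                fh.write("\t".join(row) + "\n")


@dataclass(frozen=True)
class SolveResult:
    """Outcome of an editing solver: the edit set, its size (the objective k),
    the resulting core-periphery partition, and provenance."""

    edits: EditSet
    objective: int
    partition: Optional[CorePeripheryPartition] = None
    optimal: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.objective != self.edits.size:
            raise ValueError("objective must equal the edit-set size")
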