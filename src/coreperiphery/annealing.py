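"""Simulated annealing for split cluster editing and monopolar editing.

The search state is a clustering of the vertices (plus, for monopolar
editing, a shared independent set).  For a fixed state the optimal number of
edge modifications is computable in linear time:

* SCE: edges between clusters are deleted; inside each cluster the cheapest
  transformation to a split graph is the splittance of the induced subgraph
  (a pure degree-sequence quantity).
* ME: edges inside the independent set and between clusters are deleted,
  missing edges inside clusters are inserted; cluster-periphery edges are
  free.

A move picks a uniform random vertex and a uniform random admissible target:
the cluster of one of its neighbors, a fresh singleton cluster, or (ME only)
the shared periphery.  A move with cost change D is accepted if D <= 0, and
otherwise with probability exp(-D/T); the temperature T falls from T0 to zero
over the course of each restart.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .graph import EditSet, Graph, apply_edits
from .recognition import (
    check_annotated_monopolar,
    is_split_cluster,
    split_partition,
    splittance,
)
from .graph import induced_subgraph
from .results import CorePeripheryPartition, SolveResult

__all__ = [
    "AnnealConfig",
    "sce_cost",
    "me_cost",
    "anneal_sce",
    "anneal_me",
    "sce_edits_from_clustering",
    "me_edits_from_state",
]


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule parameters (defaults follow the reference protocol:
    20,000 steps per restart, initial temperature 1, 100 restarts)."""

    steps: int = 20_000
    t0: float = 1.0
    restarts: int = 100
    seed: int = 0
    cooling: str = "linear"  # or "geometric"
    geometric_ratio: float = 0.9995
    debug_check: bool = False  # re-derive the cached cost after every accept

    def __post_init__(self):
        if self.steps < 1 or self.restarts < 1 or self.t0 <= 0:
            raise ValueError("steps >= 1, restarts >= 1, t0 > 0 required")
        if self.cooling not in ("linear", "geometric"):
            raise ValueError(f"unknown cooling schedule {self.cooling!r}")

    def temperature(self, t: int) -> float:
        if self.cooling == "linear":
            return self.t0 * (1.0 - t / self.steps)
        return self.t0 * self.geometric_ratio ** t


def _normalize_clustering(g: Graph, clustering) -> list[set]:
    if isinstance(clustering, Mapping):
        groups: dict = {}
        for v, cid in clustering.items():
            groups.setdefault(cid, set()).add(v)
        clusters = [set(s) for s in groups.values()]
    else:
        clusters = [set(c) for c in clustering]
    return clusters


def _check_partition(g: Graph, parts: Iterable[set], what: str) -> None:
    seen: set = set()
    for p in parts:
        if p & seen:
            raise ValueError(f"{what} blocks are not disjoint")
        seen |= p
    if seen != set(g.vertices):
        raise ValueError(f"{what} does not cover the vertex set")


def _subset_splittance(g: Graph, s: set) -> int:
    degs = [len(g.neighbors(u) & s) for u in s]
    d = sorted(degs, reverse=True)
    k = 0
    for i, di in enumerate(d, start=1):
        if di >= i - 1:
            k = i
    return (k * (k - 1) - sum(d[:k]) + sum(d[k:])) // 2


def sce_cost(g: Graph, clustering) -> int:
    """Edges between clusters plus the splittance of every induced cluster."""
    clusters = _normalize_clustering(g, clustering)
    _check_partition(g, clusters, "clustering")
    where = {v: i for i, c in enumerate(clusters) for v in c}
    inter = sum(1 for e in g.edges if len({where[v] for v in e}) == 2)
    return inter + sum(_subset_splittance(g, c) for c in clusters)


def me_cost(g: Graph, clustering, periphery) -> int:
    """Periphery-internal edges + inter-cluster edges + missing edges within
    clusters; cluster-periphery edges cost nothing."""
    clusters = _normalize_clustering(g, clustering)
    peri = set(periphery)
    _check_partition(g, clusters + [peri], "clustering+periphery")
    where = {v: i for i, c in enumerate(clusters) for v in c}
    pp = inter = within = 0
    for e in g.edges:
        u, v = tuple(e)
        if u in peri and v in peri:
            pp += 1
        elif u in peri or v in peri:
            continue
        elif where[u] == where[v]:
            within += 1
        else:
            inter += 1
    missing = sum(len(c) * (len(c) - 1) // 2 for c in clusters) - within
    return pp + inter + missing


# -- edit-set reconstruction for a fixed state -----------------------------

def sce_edits_from_clustering(
    g: Graph, clusters: list[set]
) -> tuple[EditSet, CorePeripheryPartition]:
    """The concrete optimal edit set for a fixed SCE clustering, together with
    the per-cluster core/periphery partition (from the splittance witness)."""
    where = {v: i for i, c in enumerate(clusters) for v in c}
    deletions = {e for e in g.edges if len({where[v] for v in e}) == 2}
    insertions: set = set()
    parts = []
    for c in sorted(clusters, key=min):
        sub = induced_subgraph(g, c)
        ap, _ = split_partition(sub)
        core, peri = ap.core, ap.periphery
        for u in core:
            for w in core:
                if u < w and not g.has_edge(u, w):
                    insertions.add(frozenset((u, w)))
        for e in g.edges:
            if e <= peri:
                deletions.add(e)
        parts.append((core, peri))
    edits = EditSet(frozenset(insertions), frozenset(deletions))
    edited = apply_edits(g, edits)
    partition = CorePeripheryPartition(
        clusters=tuple(parts), mode="per_cluster", graph=edited
    )
    return edits, partition


def me_edits_from_state(
    g: Graph, clusters: list[set], periphery: set
) -> tuple[EditSet, CorePeripheryPartition]:
    """The concrete optimal edit set for a fixed ME state."""
    where = {v: i for i, c in enumerate(clusters) for v in c}
    deletions: set = set()
    insertions: set = set()
    for e in g.edges:
        u, v = tuple(e)
        if u in periphery and v in periphery:
            deletions.add(e)
        elif u in periphery or v in periphery:
            continue
        elif where[u] != where[v]:
            deletions.add(e)
    for c in clusters:
        for u in c:
            for w in c:
                if u < w and not g.has_edge(u, w):
                    insertions.add(frozenset((u, w)))
    edits = EditSet(frozenset(insertions), frozenset(deletions))
    edited = apply_edits(g, edits)
    partition = CorePeripheryPartition(
        clusters=tuple(
            (frozenset(c), frozenset())
            for c in sorted((c for c in clusters if c), key=min)
        ),
        shared_periphery=frozenset(periphery),
        mode="shared",
        graph=edited,
    )
    return edits, partition


# -- annealing proper ------------------------------------------------------

_RETRIES = 5  # redraws when a proposed move is inadmissible / a no-op


def anneal_sce(g: Graph, cfg: AnnealConfig = AnnealConfig()) -> SolveResult:
    """Simulated annealing for split cluster editing.

    Each restart begins from the all-singletons clustering.  Deterministic
    for a fixed seed.
    """
    rng = random.Random(cfg.seed)
    vs = g.sorted_vertices()
    if not vs:
        return SolveResult(
            edits=EditSet(),
            objective=0,
            partition=CorePeripheryPartition(clusters=(), graph=g),
            optimal=True,
            provenance={"solver": "anneal_sce"},
        )
    adj = {v: g.neighbors(v) for v in vs}

    best_cost: Optional[int] = None
    best_clusters: Optional[list[frozenset]] = None

    for _ in range(cfg.restarts):
        clusters: dict[int, set] = {i: {v} for i, v in enumerate(vs)}
        cluster_of = {v: i for i, v in enumerate(vs)}
        spl = {i: 0 for i in clusters}
        next_id = len(vs)
        inter = g.m  # all edges start between singleton clusters
        cost = inter  # all splittances are zero

        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_clusters = [frozenset(c) for c in clusters.values()]

        for t in range(cfg.steps):
            T = cfg.temperature(t)
            for _try in range(_RETRIES):
                v = vs[rng.randrange(len(vs))]
                a = cluster_of[v]
                targets = sorted({cluster_of[u] for u in adj[v]} - {a})
                if len(clusters[a]) > 1:
                    targets.append(-1)  # fresh empty cluster
                if targets:
                    break
            else:
                continue
            b = targets[rng.randrange(len(targets))]

            ca = clusters[a]
            e_va = len(adj[v] & ca)
            cb = clusters[b] if b != -1 else set()
            e_vb = len(adj[v] & cb)
            spl_a_new = _subset_splittance(g, ca - {v})
            spl_b_new = _subset_splittance(g, cb | {v})
            delta = (
                spl_a_new + spl_b_new - spl[a] - (spl[b] if b != -1 else 0)
                + e_va - e_vb
            )
            if delta > 0 and (T <= 0 or rng.random() >= math.exp(-delta / T)):
                continue
            # apply
            ca.remove(v)
            spl[a] = spl_a_new
            if not ca:
                del clusters[a], spl[a]
            if b == -1:
                b = next_id
                next_id += 1
                clusters[b] = set()
            clusters[b].add(v)
            spl[b] = spl_b_new
            cluster_of[v] = b
            inter += e_va - e_vb
            cost += delta
            if cfg.debug_check:
                assert cost == sce_cost(g, list(clusters.values()))
            if cost < best_cost:
                best_cost = cost
                best_clusters = [frozenset(c) for c in clusters.values()]

    edits, partition = sce_edits_from_clustering(g, [set(c) for c in best_clusters])
    assert edits.size == best_cost, (edits.size, best_cost)
    ok, _cert = is_split_cluster(partition.graph)
    assert ok
    return SolveResult(
        edits=edits,
        objective=edits.size,
        partition=partition,
        optimal=False,
        provenance={"solver": "anneal_sce", "restarts": cfg.restarts,
                    "steps": cfg.steps, "seed": cfg.seed},
    )


def anneal_me(g: Graph, cfg: AnnealConfig = AnnealConfig()) -> SolveResult:
    """Simulated annealing for monopolar editing: as :func:`anneal_sce` with
    the extra move type 'move the vertex into the shared periphery'."""
    rng = random.Random(cfg.seed)
    vs = g.sorted_vertices()
    if not vs:
        return SolveResult(
            edits=EditSet(),
            objective=0,
            partition=CorePeripheryPartition(clusters=(), mode="shared", graph=g),
            optimal=True,
            provenance={"solver": "anneal_me"},
        )
    adj = {v: g.neighbors(v) for v in vs}

    best_cost: Optional[int] = None
    best_state: Optional[tuple] = None

    for _ in range(cfg.restarts):
        clusters: dict[int, set] = {i: {v} for i, v in enumerate(vs)}
        cluster_of: dict[str, Optional[int]] = {v: i for i, v in enumerate(vs)}
        within = {i: 0 for i in clusters}
        periphery: set = set()
        next_id = len(vs)
        pp = 0
        inter = g.m
        cost = inter  # no missing edges inside singletons, empty periphery

        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_state = ([frozenset(c) for c in clusters.values()], frozenset())

        for t in range(cfg.steps):
            T = cfg.temperature(t)
            for _try in range(_RETRIES):
                v = vs[rng.randrange(len(vs))]
                a = cluster_of[v]  # None if in periphery
                nb_clusters = sorted(
                    {cluster_of[u] for u in adj[v] if cluster_of[u] is not None}
                    - {a}
                )
                targets: list = list(nb_clusters)
                if a is None or len(clusters[a]) > 1:
                    targets.append(-1)  # fresh singleton cluster
                if a is not None:
                    targets.append(-2)  # shared periphery
                if targets:
                    break
            else:
                continue
            b = targets[rng.randrange(len(targets))]

            cl_deg = sum(1 for u in adj[v] if cluster_of[u] is not None)
            e_vp = len(adj[v] & periphery)
            if a is not None:
                ca = clusters[a]
                e_va = len(adj[v] & ca)
                sz_a = len(ca)
            if b == -2:
                # cluster -> periphery
                delta = 2 * e_va - (sz_a - 1) - cl_deg + e_vp
            elif a is None:
                # periphery -> cluster b (possibly fresh)
                cb = clusters[b] if b != -1 else set()
                e_vb = len(adj[v] & cb)
                delta = cl_deg - 2 * e_vb + len(cb) - e_vp
            else:
                # cluster -> cluster
                cb = clusters[b] if b != -1 else set()
                e_vb = len(adj[v] & cb)
                delta = 2 * e_va - 2 * e_vb + len(cb) - (sz_a - 1)
            if delta > 0 and (T <= 0 or rng.random() >= math.exp(-delta / T)):
                continue
            # apply
            if a is not None:
                ca.remove(v)
                within[a] -= e_va
                if not ca:
                    del clusters[a], within[a]
            else:
                periphery.remove(v)
                pp -= e_vp
            if b == -2:
                periphery.add(v)
                pp += e_vp
                inter -= cl_deg - e_va
                cluster_of[v] = None
            else:
                if b == -1:
                    b = next_id
                    next_id += 1
                    clusters[b] = set()
                    within[b] = 0
                e_vb = len(adj[v] & clusters[b])
                clusters[b].add(v)
                within[b] += e_vb
                cluster_of[v] = b
                if a is not None:
                    inter += e_va - e_vb
                else:
                    inter += cl_deg - e_vb
            cost += delta
            if cfg.debug_check:
                assert cost == me_cost(g, list(clusters.values()), periphery)
            if cost < best_cost:
                best_cost = cost
                best_state = (
                    [frozenset(c) for c in clusters.values()],
                    frozenset(periphery),
                )

    best_cl, best_peri = best_state
    edits, partition = me_edits_from_state(
        g, [set(c) for c in best_cl], set(best_peri)
    )
    assert edits.size == best_cost, (edits.size, best_cost)
    from .recognition import AnnotatedPartition

    ok, _ = check_annotated_monopolar(
        partition.graph,
        AnnotatedPartition(
            core=partition.graph.vertices - partition.shared_periphery,
            periphery=partition.shared_periphery,
        ),
    )
    assert ok
    return SolveResult(
        edits=edits,
        objective=edits.size,
        partition=partition,
        optimal=False,
        provenance={"solver": "anneal_me", "restarts": cfg.restarts,
                    "steps": cfg.steps, "seed": cfg.seed},
    )
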