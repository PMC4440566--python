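"""Seeded generators for test instances.

Two families: Erdos-Renyi random graphs (each possible edge present
independently with probability p), which stress-test the solvers, and planted
core-periphery instances that realize the two formal models exactly - disjoint
split components (the split-cluster model) or disjoint cliques sharing one
independent periphery (the monopolar model) - optionally perturbed by a fixed
number of uniformly chosen edge toggles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graph import EditSet, Graph, apply_edits
from .results import CorePeripheryPartition

__all__ = ["PlantedInstance", "er_graph", "planted_instance", "perturb"]


@dataclass(frozen=True)
class PlantedInstance:
    """A generated graph with its ground-truth partition.

    Before any noise is applied, ``graph`` passes the recognizer matching
    ``model`` ('disjoint' -> split cluster graph, 'shared_periphery' ->
    monopolar) with partition ``truth``.
    """

    graph: Graph
    truth: CorePeripheryPartition
    model: str
    applied_noise: EditSet


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def er_graph(n: int, p: float, seed) -> Graph:
    """Erdos-Renyi G(n, p) with zero-padded labels v00, v01, ... (lexicographic
    label order equals numeric order)."""
    if not 0 <= p <= 1:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = _rng(seed)
    width = max(2, len(str(max(n - 1, 0))))
    labels = [f"v{i:0{width}d}" for i in range(n)]
    pairs = list(itertools.combinations(labels, 2))
    if pairs:
        mask = rng.random(len(pairs)) < p
        edges = [pr for pr, keep in zip(pairs, mask) if keep]
    else:
        edges = []
    return Graph(labels, edges)


def planted_instance(
    core_sizes: Sequence[int],
    periphery_sizes: Sequence[int],
    model: str = "disjoint",
    attach_prob: float = 0.5,
    seed=None,
) -> PlantedInstance:
    """A noiseless planted core-periphery instance.

    Cores are disjoint complete cliques.  Periphery vertices are an
    independent set; each one gains an edge to a core vertex with probability
    ``attach_prob`` per candidate (its own core in the ``disjoint`` model, any
    core vertex in the ``shared_periphery`` model), redrawing until it has at
    least one attachment.
    """
    if model not in ("disjoint", "shared_periphery"):
        raise ValueError(f"unknown model {model!r}")
    if not 0 < attach_prob <= 1:
        raise ValueError("attach_prob must be in (0, 1]")
    if any(s <= 0 for s in core_sizes):
        raise ValueError("core sizes must be positive")
    if model == "disjoint" and len(periphery_sizes) != len(core_sizes):
        raise ValueError("disjoint model needs one periphery size per core")
    rng = _rng(seed)

    cores = [
        [f"c{i}_{j}" for j in range(sz)] for i, sz in enumerate(core_sizes)
    ]
    edges: list[tuple[str, str]] = []
    for members in cores:
        edges.extend(itertools.combinations(members, 2))

    def attach(vertex: str, candidates: list[str]) -> list[tuple[str, str]]:
        while True:
            mask = rng.random(len(candidates)) < attach_prob
            if mask.any():
                return [(vertex, c) for c, keep in zip(candidates, mask) if keep]

    vertices = [v for members in cores for v in members]
    if model == "disjoint":
        clusters = []
        for i, (members, psz) in enumerate(zip(cores, periphery_sizes)):
            peri = [f"p{i}_{j}" for j in range(psz)]
            vertices.extend(peri)
            for v in peri:
                edges.extend(attach(v, members))
            clusters.append((frozenset(members), frozenset(peri)))
        g = Graph(vertices, edges)
        truth = CorePeripheryPartition(
            clusters=tuple(clusters), mode="per_cluster", graph=g
        )
    else:
        all_core = [v for members in cores for v in members]
        peri = [f"p{j}" for j in range(sum(periphery_sizes))]
        vertices.extend(peri)
        for v in peri:
            edges.extend(attach(v, all_core))
        g = Graph(vertices, edges)
        truth = CorePeripheryPartition(
            clusters=tuple((frozenset(members), frozenset()) for members in cores),
            shared_periphery=frozenset(peri),
            mode="shared",
            graph=g,
        )
    return PlantedInstance(
        graph=g, truth=truth, model=model, applied_noise=EditSet()
    )


def perturb(g: Graph, num_edits: int, seed) -> tuple[Graph, EditSet]:
    """Toggle ``num_edits`` distinct vertex pairs chosen uniformly without
    replacement; returns the perturbed graph and the applied edit set."""
    pairs = [frozenset(p) for p in itertools.combinations(g.sorted_vertices(), 2)]
    if num_edits > len(pairs):
        raise ValueError("more edits requested than vertex pairs")
    rng = _rng(seed)
    chosen = rng.choice(len(pairs), size=num_edits, replace=False)
    toggled = [pairs[i] for i in chosen]
    edits = EditSet(
        insertions=frozenset(p for p in toggled if p not in g.edges),
        deletions=frozenset(p for p in toggled if p in g.edges),
    )
    return apply_edits(g, edits), edits
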