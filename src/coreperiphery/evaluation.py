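"""Cluster statistics and protein-complex detection scoring.

Given a core-periphery partition and a set of gold-standard complexes
(e.g. CYC2008), complexes are first filtered against the analyzed
subnetwork: drop complexes with less than 50% of their members present,
restrict the rest to present members, then drop those with fewer than three.
A complex is *detected* by a cluster if at least 50% of the cluster's core
belongs to the complex and at least 50% of the complex belongs to the
cluster.  A cluster is *nontrivial* if it has at least three vertices and at
least two core vertices; detection is scored over nontrivial clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Optional

import pandas as pd

from .graph import EditSet, Graph
from .results import CorePeripheryPartition

__all__ = [
    "ComplexSet",
    "read_complexes",
    "filter_complexes",
    "nontrivial_clusters",
    "detect_complexes",
    "partition_stats",
]


@dataclass(frozen=True)
class ComplexSet:
    """Named families of vertex labels (gold-standard complexes)."""

    complexes: dict

    def __post_init__(self):
        norm = {str(k): frozenset(v) for k, v in self.complexes.items()}
        if any(not v for v in norm.values()):
            raise ValueError("complexes must be nonempty")
        object.__setattr__(self, "complexes", norm)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(sorted(self.complexes))

    def __getitem__(self, name: str) -> frozenset:
        return self.complexes[name]


def read_complexes(path) -> ComplexSet:
    """One complex per line: name, then tab-separated member labels."""
    out = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: complex line needs a name and members")
            out[fields[0]] = frozenset(fields[1:])
    return ComplexSet(out)


def filter_complexes(cx: ComplexSet, g: Graph) -> ComplexSet:
    """Drop complexes with <50% of members in ``g``, restrict the survivors
    to members present in ``g``, then drop those with fewer than three."""
    present = set(g.vertices)
    kept = {}
    for name in cx:
        members = cx[name]
        inside = members & present
        if len(inside) * 2 < len(members):
            continue
        if len(inside) < 3:
            continue
        kept[name] = inside
    return ComplexSet(kept)


def nontrivial_clusters(
    p: CorePeripheryPartition, graph: Optional[Graph] = None
) -> list[int]:
    """Indices of clusters with >= 3 vertices (core plus effective periphery)
    and >= 2 core vertices."""
    out = []
    for i, (core, _) in enumerate(p.clusters):
        if len(core) < 2:
            continue
        if len(p.cluster_vertices(i, graph)) < 3:
            continue
        out.append(i)
    return out


def detect_complexes(
    p: CorePeripheryPartition, cx: ComplexSet, graph: Optional[Graph] = None
) -> dict:
    """Detection report over the (already filtered) complex set.

    Per complex: a detected flag and, from the best-scoring detecting
    cluster, core_% (core vertices inside the complex), comp_% (complex
    members inside the cluster) and extra_% (periphery vertices outside the
    complex; 0 for an empty periphery).  A complex counts once even when
    several clusters detect it.  Aggregates are the mean and median over
    detected complexes.
    """
    candidates = nontrivial_clusters(p, graph)
    per_complex = {}
    for name in cx:
        members = cx[name]
        best = None
        for i in candidates:
            core, _ = p.clusters[i]
            peri = p.effective_periphery(i, graph)
            cluster_vertices = core | peri
            core_frac = len(core & members) / len(core)
            comp_frac = len(members & cluster_vertices) / len(members)
            if core_frac < 0.5 or comp_frac < 0.5:
                continue
            extra_frac = (
                len(peri - members) / len(peri) if peri else 0.0
            )
            score = (core_frac + comp_frac, -extra_frac, -i)
            if best is None or score > best[0]:
                best = (score, i, core_frac, comp_frac, extra_frac)
        if best is None:
            per_complex[name] = {"detected": False}
        else:
            _, i, core_frac, comp_frac, extra_frac = best
            per_complex[name] = {
                "detected": True,
                "cluster": i,
                "core_pct": 100.0 * core_frac,
                "comp_pct": 100.0 * comp_frac,
                "extra_pct": 100.0 * extra_frac,
            }
    detected = [d for d in per_complex.values() if d["detected"]]
    report = {"per_complex": per_complex, "D": len(detected)}
    for key in ("core_pct", "comp_pct", "extra_pct"):
        vals = [d[key] for d in detected]
        report[f"{key}_mean"] = mean(vals) if vals else None
        report[f"{key}_median"] = median(vals) if vals else None
    return report


def partition_stats(
    p: CorePeripheryPartition,
    edits: Optional[EditSet] = None,
    graph: Optional[Graph] = None,
) -> dict:
    """Solution statistics: k (edit count), K (nontrivial clusters), and the
    mean core and periphery sizes over nontrivial clusters."""
    nt = nontrivial_clusters(p, graph)
    cores = [len(p.clusters[i][0]) for i in nt]
    peris = [len(p.effective_periphery(i, graph)) for i in nt]
    return {
        "k": edits.size if edits is not None else None,
        "K": len(nt),
        "core_mean": mean(cores) if cores else None,
        "periphery_mean": mean(peris) if peris else None,
    }


def stats_frame(reports: dict) -> pd.DataFrame:
    """Tabulate {method: stats dict} as a tidy frame (mirrors the usual
    solution-statistics table layout)."""
    return pd.DataFrame(reports).T
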