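"""Shared fixtures: small named graphs and seeded random suites."""

import pytest

from coreperiphery.graph import Graph


def G(edge_spec: str, extra_vertices: str = "") -> Graph:
    """Build a graph from 'ab bc cd' style edge spec (one char per vertex)."""
    edges = [(e[0], e[1]) for e in edge_spec.split()]
    return Graph(list(extra_vertices), edges)


NAMED = {
    "K1": Graph("a"),
    "K2": G("ab"),
    "K3": G("ab bc ac"),
    "K4": G("ab ac ad bc bd cd"),
    "P3": G("ab bc"),
    "P4": G("ab bc cd"),
    "P5": G("ab bc cd de"),
    "P6": G("ab bc cd de ef"),
    "C4": G("ab bc cd da"),
    "C5": G("ab bc cd de ea"),
    "2K2": G("ab cd"),
    # triangle a-b-v plus path v-c-d
    "necktie": G("ab av bv vc cd"),
    # two triangles sharing v
    "bowtie": G("ab av bv cd cv dv"),
    # 4-cycle b-c-d-e plus hub a
    "W4": G("ab ac ad ae bc cd de eb"),
    "star": G("ax ay az"),
    "two_triangles": G("ab bc ac de ef df"),
}


@pytest.fixture
def named_graphs():
    return NAMED


@pytest.fixture(params=sorted(NAMED))
def any_named_graph(request):
    return NAMED[request.param]
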