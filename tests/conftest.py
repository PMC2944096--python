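from __future__ import annotations

import networkx as nx
import pytest

import vulnstrat as vs


@pytest.fixture(scope="session")
def worcester():
    """The packaged Worcester County table with its published partition."""
    return vs.load_worcester_fixture()


@pytest.fixture(scope="session")
def worcester_table():
    return vs.load_worcester_table()


@pytest.fixture()
def path6_area():
    """Six towns on a path, identical indices, equal MOS."""
    units = [
        vs.SpatialUnit(unit_id=f"u{i}", name=f"u{i}", mos=100.0, h_s=5.0, a_s=5.0)
        for i in range(6)
    ]
    g = nx.path_graph([f"u{i}" for i in range(6)])
    return vs.StudyArea(units, adjacency=g)


def make_area(mos, h, a, graph):
    """Toy StudyArea from per-unit dicts keyed like the graph's nodes."""
    units = [
        vs.SpatialUnit(unit_id=str(u), name=str(u), mos=mos[u], h_s=h[u], a_s=a[u])
        for u in graph.nodes
    ]
    return vs.StudyArea(units, adjacency=nx.relabel_nodes(graph, {u: str(u) for u in graph.nodes}))
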