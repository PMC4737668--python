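"""Shared fixtures and independent test oracles.

The oracles here deliberately avoid the package's own machinery wherever
an independent route exists: isomorphism deduplication and containment go
through networkx's VF2 matcher, pattern lattices are enumerated by brute
force over connected edge subsets, and scores are dense quadratic forms.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from gmsv.graph_core import GraphDataset, LabeledGraph
from gmsv.side_views import SideView
from gmsv.synthetic import SimulationConfig, ViewSpec

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture6"


def fixture_config() -> SimulationConfig:
    """The committed 6-subject test corpus: 12 regions, planted triangle."""
    return SimulationConfig(
        n_pos=3,
        n_neg=3,
        n_nodes=12,
        edge_density=0.2,
        planted_pattern=LabeledGraph({0: 1, 1: 4, 2: 7}, [(0, 1), (1, 2), (0, 2)]),
        views=[ViewSpec(3, 1.0, 1.0), ViewSpec(2, 0.5, 1.0)],
        seed=7,
    )


def to_networkx(g: LabeledGraph) -> nx.Graph:
    out = nx.Graph()
    for v, lab in g.labels.items():
        out.add_node(v, label=lab)
    for u, v, le in g.edges():
        out.add_edge(u, v, label=le)
    return out


_NODE_MATCH = nx.algorithms.isomorphism.categorical_node_match("label", None)
_EDGE_MATCH = nx.algorithms.isomorphism.categorical_edge_match("label", None)


def nx_isomorphic(a: LabeledGraph, b: LabeledGraph) -> bool:
    return nx.is_isomorphic(
        to_networkx(a), to_networkx(b), node_match=_NODE_MATCH, edge_match=_EDGE_MATCH
    )


def nx_contains(host: LabeledGraph, pattern: LabeledGraph) -> bool:
    """Label-preserving (non-induced) subgraph containment via VF2."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        to_networkx(host), to_networkx(pattern),
        node_match=_NODE_MATCH, edge_match=_EDGE_MATCH,
    )
    return gm.subgraph_is_monomorphic()


def connected_subgraphs(g: LabeledGraph):
    """Every connected subgraph of g: single vertices plus connected edge subsets."""
    for v, lab in g.labels.items():
        yield LabeledGraph([lab])
    edges = list(g.edge_labels.items())
    for r in range(1, len(edges) + 1):
        for subset in combinations(edges, r):
            verts = sorted({v for (u, w), _ in subset for v in (u, w)})
            sub = LabeledGraph(
                {v: g.labels[v] for v in verts},
                [(u, w, le) for (u, w), le in subset],
            )
            if sub.is_connected():
                yield sub


def lattice_frequent(dataset: GraphDataset, thresh: int):
    """Brute-force frequent-pattern oracle.

    Enumerates all connected subgraphs of every graph, deduplicates by
    VF2 isomorphism, computes supports by VF2 containment, and filters by
    the absolute support threshold.  Returns (pattern, support) pairs.
    """
    buckets: dict[tuple, list[LabeledGraph]] = {}
    for g in dataset.graphs:
        for sub in connected_subgraphs(g):
            key = (
                sub.label_multiset(),
                tuple(sorted(
                    tuple(sorted((sub.labels[u], sub.labels[v]))) + (le,)
                    for u, v, le in sub.edges()
                )),
            )
            group = buckets.setdefault(key, [])
            if not any(nx_isomorphic(sub, other) for other in group):
                group.append(sub)
    out = []
    for group in buckets.values():
        for pattern in group:
            support = tuple(
                j for j, host in enumerate(dataset.graphs) if nx_contains(host, pattern)
            )
            if len(support) >= thresh:
                out.append((pattern, support))
    return out


def random_small_dataset(
    rng: np.random.Generator,
    n: int = 20,
    max_nodes: int = 8,
    max_edges: int = 10,
    n_labels: int = 4,
    n_views: int = 2,
) -> tuple[GraphDataset, list[SideView]]:
    """Small random labeled-graph dataset with Gaussian side views."""
    graphs = []
    for _ in range(n):
        nv = int(rng.integers(2, max_nodes + 1))
        labels = rng.integers(0, n_labels, size=nv)
        pairs = [(u, v) for u in range(nv) for v in range(u + 1, nv)]
        rng.shuffle(pairs)
        ne = int(rng.integers(1, min(max_edges, len(pairs)) + 1))
        graphs.append(LabeledGraph(list(labels), pairs[:ne]))
    y = rng.choice([-1, 1], size=n)
    while len(set(y.tolist())) < 2:
        y = rng.choice([-1, 1], size=n)
    views = [
        SideView(rng.normal(size=(n, d))) for d in rng.integers(2, 5, size=n_views)
    ]
    return GraphDataset(graphs, y), views


@pytest.fixture
def toy_edge_dataset() -> GraphDataset:
    """Three identical single-edge graphs with labels 1–2 and mixed classes."""
    g = LabeledGraph([1, 2], [(0, 1)])
    return GraphDataset([g, g, g], np.array([1, -1, 1]))
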