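"""Labeled graphs, graph datasets, and subgraph patterns.

The data model here is the "primary view" of a multi-view graph
classification problem: each subject is an undirected simple graph whose
vertices carry integer labels (for brain networks, the atlas region index)
and whose edges optionally carry integer labels.  Subgraph containment is
label-preserving subgraph isomorphism: a pattern is contained in a host
graph iff there is an injective, label-preserving vertex map under which
every pattern edge maps to a host edge.

The brute-force isomorphism oracle in this module is exponential in the
pattern size and is intended for small patterns (and as an independent
check of the miner's embedding-list support counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "LabeledGraph",
    "GraphDataset",
    "SubgraphPattern",
    "is_subgraph_isomorphic",
    "compute_support",
]


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u <= v else (v, u)


class LabeledGraph:
    """Undirected simple graph with integer vertex (and edge) labels.

    Parameters
    ----------
    vertex_labels
        Mapping from vertex ID to integer label, or a sequence of labels
        (in which case vertex IDs are ``0..len-1``).
    edges
        Iterable of ``(u, v)`` or ``(u, v, edge_label)`` tuples.  The
        default edge label is 0.  Self-loops and parallel edges are
        rejected; endpoints must be declared vertices.
    """

    __slots__ = ("labels", "edge_labels", "adj")

    def __init__(
        self,
        vertex_labels: Mapping[int, int] | Sequence[int],
        edges: Iterable[tuple] = (),
    ) -> None:
        if isinstance(vertex_labels, Mapping):
            self.labels: dict[int, int] = {int(v): int(l) for v, l in vertex_labels.items()}
        else:
            self.labels = {i: int(l) for i, l in enumerate(vertex_labels)}
        self.edge_labels: dict[tuple[int, int], int] = {}
        self.adj: dict[int, dict[int, int]] = {v: {} for v in self.labels}
        for e in edges:
            if len(e) == 2:
                u, v = e
                le = 0
            else:
                u, v, le = e
            u, v, le = int(u), int(v), int(le)
            if u == v:
                raise ValueError(f"self-loop on vertex {u} not allowed")
            if u not in self.labels or v not in self.labels:
                raise ValueError(f"edge ({u},{v}) references an undeclared vertex")
            key = _edge_key(u, v)
            if key in self.edge_labels:
                raise ValueError(f"parallel edge ({u},{v})")
            self.edge_labels[key] = le
            self.adj[u][v] = le
            self.adj[v][u] = le

    # -- basic accessors -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_labels)

    def vertices(self) -> Iterator[int]:
        return iter(self.labels)

    def edges(self) -> Iterator[tuple[int, int, int]]:
        for (u, v), le in self.edge_labels.items():
            yield u, v, le

    def has_edge(self, u: int, v: int) -> bool:
        return _edge_key(u, v) in self.edge_labels

    def is_connected(self) -> bool:
        if not self.labels:
            return False
        start = next(iter(self.labels))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in self.adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(self.labels)

    # -- comparisons -----------------------------------------------------

    def label_multiset(self) -> tuple:
        """Sorted (vertex label, degree) pairs — a cheap isomorphism invariant."""
        return tuple(sorted((self.labels[v], len(self.adj[v])) for v in self.labels))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"LabeledGraph(|V|={self.n_vertices}, |E|={self.n_edges}, "
            f"labels={sorted(self.labels.values())})"
        )


@dataclass
class GraphDataset:
    """An ordered collection of labeled graphs with class labels.

    ``labels`` take values in {-1, +1} with 0 meaning unlabeled.  Subject
    IDs are unique strings aligned with ``graphs``; all index-based
    structures downstream (kernel rows, indicator vectors) follow this
    order.
    """

    graphs: list[LabeledGraph]
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.graphs) < 1:
            raise ValueError("dataset must contain at least one graph")
        if self.labels.shape != (len(self.graphs),):
            raise ValueError("labels vector length must equal the number of graphs")
        if not np.all(np.isin(self.labels, (-1, 0, 1))):
            raise ValueError("labels must be -1, +1, or 0 (unlabeled)")
        if not self.ids:
            self.ids = [f"g{i}" for i in range(len(self.graphs))]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("subject IDs must be unique")

    def __len__(self) -> int:
        return len(self.graphs)

    def subset(self, indices: Sequence[int]) -> "GraphDataset":
        idx = list(indices)
        return GraphDataset(
            graphs=[self.graphs[i] for i in idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
        )


@dataclass(frozen=True)
class SubgraphPattern:
    """A connected subgraph pattern together with its occurrence footprint.

    ``support`` is the sorted tuple of dataset indices of the graphs that
    contain the pattern; ``indicator`` is the aligned binary vector f with
    ``f[j] = 1`` iff graph j contains the pattern.
    """

    graph: LabeledGraph
    support: tuple[int, ...]
    n: int
    code: tuple | None = None

    def __post_init__(self) -> None:
        if tuple(sorted(self.support)) != self.support:
            object.__setattr__(self, "support", tuple(sorted(self.support)))

    @property
    def indicator(self) -> np.ndarray:
        f = np.zeros(self.n, dtype=np.int8)
        if self.support:
            f[list(self.support)] = 1
        return f

    @property
    def frequency(self) -> float:
        return len(self.support) / self.n


def _match_extend(
    pattern: LabeledGraph,
    host: LabeledGraph,
    order: list[int],
    mapping: dict[int, int],
    used: set[int],
) -> bool:
    if len(mapping) == len(order):
        return True
    pv = order[len(mapping)]
    pl = pattern.labels[pv]
    # candidates: host vertices with matching label, not yet used, adjacent
    # consistently with already-mapped pattern neighbours
    mapped_nbrs = [(q, le) for q, le in pattern.adj[pv].items() if q in mapping]
    if mapped_nbrs:
        # anchor on one mapped neighbour to restrict candidates
        q0, le0 = mapped_nbrs[0]
        candidates = [
            h for h, hle in host.adj[mapping[q0]].items() if hle == le0 and h not in used
        ]
    else:
        candidates = [h for h in host.labels if h not in used]
    for h in candidates:
        if host.labels[h] != pl:
            continue
        ok = True
        for q, le in mapped_nbrs:
            hq = mapping[q]
            if host.adj[h].get(hq) != le:
                ok = False
                break
        if not ok:
            continue
        mapping[pv] = h
        used.add(h)
        if _match_extend(pattern, host, order, mapping, used):
            del mapping[pv]
            used.discard(h)
            return True
        del mapping[pv]
        used.discard(h)
    return False


def is_subgraph_isomorphic(pattern: LabeledGraph, host: LabeledGraph) -> bool:
    """Label-preserving subgraph-isomorphism test (pattern ⊆ host).

    The pattern must be connected and non-empty.  Backtracking with
    label/adjacency filtering; exponential worst case, fine for the small
    patterns this package mines.
    """
    if pattern.n_vertices == 0:
        raise ValueError("empty pattern is not a valid subgraph")
    if not pattern.is_connected():
        raise ValueError("pattern must be connected")
    if pattern.n_vertices > host.n_vertices or pattern.n_edges > host.n_edges:
        return False
    # DFS order over pattern vertices so every vertex after the first has a
    # previously-mapped neighbour (the pattern is connected)
    start = next(iter(pattern.labels))
    order = [start]
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in pattern.adj[u]:
            if w not in seen:
                seen.add(w)
                order.append(w)
                stack.append(w)
    return _match_extend(pattern, host, order, {}, set())


def compute_support(pattern: LabeledGraph, dataset: GraphDataset) -> SubgraphPattern:
    """Occurrence footprint of ``pattern`` across a dataset via the oracle."""
    support = tuple(
        j for j, g in enumerate(dataset.graphs) if is_subgraph_isomorphic(pattern, g)
    )
    return SubgraphPattern(graph=pattern, support=support, n=len(dataset))
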