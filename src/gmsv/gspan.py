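"""Canonical subgraph enumeration via gSpan DFS codes.

A connected pattern is encoded as an ordered sequence of edge tuples
``(i, j, l_i, l_e, l_j)`` where ``i`` and ``j`` are DFS discovery indices,
``l_i``/``l_j`` vertex labels and ``l_e`` the edge label.  The first tuple
has ``(i, j) = (0, 1)``; every later tuple is either a forward edge
(``j`` equals the current max index + 1, grown from a vertex on the
rightmost path) or a backward edge (from the rightmost vertex to an
earlier vertex on the rightmost path).  Among all DFS codes of a graph the
lexicographically smallest one — under gSpan's neighbourhood order:
backward before forward, smaller backward target first, deeper forward
origin first, then labels — is its canonical form.  Enumerating only
minimum codes yields exactly one node per isomorphism class, and support
anti-monotonicity along code-tree edges makes frequency pruning sound.

The module exposes three layers:

* ``min_dfs_code`` / ``is_minimum_dfs_code`` — canonical-form machinery;
* ``dfs_walk`` — a depth-first walk of the frequent-pattern code tree that
  a visitor can prune (this is what the branch-and-bound miner drives);
* ``enumerate_frequent`` — the plain frequent-subgraph iterator.

Support is counted with embedding lists (all injective occurrences per
graph), so child support is exact without re-running an isomorphism test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

from .graph_core import GraphDataset, LabeledGraph, SubgraphPattern

__all__ = [
    "DFSEdge",
    "DFSCode",
    "WalkStats",
    "code_to_graph",
    "min_dfs_code",
    "is_minimum_dfs_code",
    "code_sort_key",
    "singleton_sort_key",
    "rightmost_extensions",
    "dfs_walk",
    "enumerate_frequent",
]

DFSEdge = tuple[int, int, int, int, int]  # (i, j, l_i, l_e, l_j)
DFSCode = tuple[DFSEdge, ...]

# embeddings: graph index -> list of tuples mapping DFS index -> host vertex
Embeddings = dict[int, list[tuple[int, ...]]]


def _ext_key(t: DFSEdge) -> tuple:
    """gSpan neighbourhood order for sibling extensions of one code.

    Backward edges precede forward edges; backward: smaller target index
    first; forward: deeper origin (larger i) first; ties broken by
    (l_i, l_e, l_j).
    """
    i, j, li, le, lj = t
    if j < i:  # backward
        return (0, j, li, le, lj)
    return (1, -i, li, le, lj)


def code_sort_key(code: DFSCode) -> tuple:
    """Deterministic total order on full DFS codes (shorter prefix first)."""
    return tuple(_ext_key(t) for t in code)


def singleton_sort_key(label: int) -> tuple:
    return ((label,),)


def _validate_code(code: DFSCode) -> None:
    if not code:
        raise ValueError("empty DFS code")
    if (code[0][0], code[0][1]) != (0, 1):
        raise ValueError("first DFS edge must be (0, 1)")
    max_idx = 1
    for i, j, *_ in code[1:]:
        if j > i:  # forward
            if j != max_idx + 1 or i > max_idx:
                raise ValueError(f"invalid forward edge ({i},{j})")
            max_idx = j
        elif j < i:  # backward
            if i != max_idx:
                raise ValueError(f"backward edge must leave the rightmost vertex: ({i},{j})")
        else:
            raise ValueError("self-loop in DFS code")


def code_to_graph(code: DFSCode) -> LabeledGraph:
    """Decode a DFS code into the pattern graph it describes (IDs = DFS indices)."""
    _validate_code(code)
    labels: dict[int, int] = {}
    edges = []
    for i, j, li, le, lj in code:
        for idx, lab in ((i, li), (j, lj)):
            if idx in labels:
                if labels[idx] != lab:
                    raise ValueError(f"inconsistent label for DFS vertex {idx}")
            else:
                labels[idx] = lab
        edges.append((i, j, le))
    return LabeledGraph(labels, edges)


def _rightmost_path(code: DFSCode) -> list[int]:
    """DFS indices from the root to the rightmost vertex."""
    parent: dict[int, int] = {}
    max_idx = 0
    for i, j, *_ in code:
        if j > i:
            parent[j] = i
            max_idx = max(max_idx, j)
    path = [max_idx]
    while path[-1] != 0:
        path.append(parent[path[-1]])
    path.reverse()
    return path


def _code_edge_set(code: DFSCode) -> set[tuple[int, int]]:
    return {(min(i, j), max(i, j)) for i, j, *_ in code}


def _dfs_labels(code: DFSCode) -> dict[int, int]:
    labels: dict[int, int] = {}
    for i, j, li, le, lj in code:
        labels[i] = li
        labels[j] = lj
    return labels


def _embedding_extensions(
    code: DFSCode,
    rm_path: list[int],
    code_edges: set[tuple[int, int]],
    dfs_labels: dict[int, int],
    emb: tuple[int, ...],
    host: LabeledGraph,
) -> Iterator[tuple[DFSEdge, tuple[int, ...]]]:
    """All one-edge rightmost-path extensions realized by one embedding."""
    vr = rm_path[-1]
    hr = emb[vr]
    in_emb = set(emb)
    # backward: rightmost vertex -> earlier vertex on the rightmost path
    for v in rm_path[:-1]:
        if (min(v, vr), max(v, vr)) in code_edges:
            continue
        le = host.adj[hr].get(emb[v])
        if le is not None:
            yield (vr, v, dfs_labels[vr], le, dfs_labels[v]), emb
    # forward: from any vertex on the rightmost path to a fresh host vertex
    new_idx = len(emb)
    for v in rm_path:
        hv = emb[v]
        for w, le in host.adj[hv].items():
            if w in in_emb:
                continue
            yield (v, new_idx, dfs_labels[v], le, host.labels[w]), emb + (w,)


def _grouped_extensions(
    code: DFSCode, embeddings: Embeddings, graphs: list[LabeledGraph]
) -> dict[DFSEdge, Embeddings]:
    rm_path = _rightmost_path(code)
    code_edges = _code_edge_set(code)
    labels = _dfs_labels(code)
    out: dict[DFSEdge, Embeddings] = {}
    for gi, embs in embeddings.items():
        host = graphs[gi]
        for emb in embs:
            for ext, new_emb in _embedding_extensions(
                code, rm_path, code_edges, labels, emb, host
            ):
                per_graph = out.setdefault(ext, {})
                lst = per_graph.setdefault(gi, [])
                if new_emb not in lst:  # backward exts can repeat per embedding set
                    lst.append(new_emb)
    return out


def rightmost_extensions(
    code: DFSCode, embeddings: Embeddings, dataset: GraphDataset
) -> list[tuple[DFSCode, Embeddings]]:
    """All realized one-edge extensions of ``code``, in canonical order.

    Returns ``(child code, child embeddings)`` pairs; child support sets
    (the keys of the embedding dict) are subsets of the parent's.
    """
    grouped = _grouped_extensions(code, embeddings, dataset.graphs)
    return [
        (code + (ext,), embs)
        for ext, embs in sorted(grouped.items(), key=lambda kv: _ext_key(kv[0]))
    ]


# ---------------------------------------------------------------------------
# canonical form


def min_dfs_code(graph: LabeledGraph) -> DFSCode:
    """Lexicographically minimum DFS code of a connected graph with ≥1 edge.

    Built greedily: at every step take the smallest realizable extension
    (under gSpan's neighbourhood order) over all embeddings of the current
    minimal prefix into the graph itself.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges; singleton patterns have no DFS code")
    if not graph.is_connected():
        raise ValueError("DFS codes are defined for connected graphs")
    # initial edge: minimum (l_i, l_e, l_j) over both orientations of all edges
    best: DFSEdge | None = None
    embs: list[tuple[int, ...]] = []
    for u, v, le in graph.edges():
        for a, b in ((u, v), (v, u)):
            t = (0, 1, graph.labels[a], le, graph.labels[b])
            if best is None or t[2:] < best[2:]:
                best = t
                embs = [(a, b)]
            elif t[2:] == best[2:]:
                embs.append((a, b))
    assert best is not None
    code: list[DFSEdge] = [best]
    while len(code) < graph.n_edges:
        rm_path = _rightmost_path(tuple(code))
        code_edges = _code_edge_set(tuple(code))
        labels = _dfs_labels(tuple(code))
        candidates: dict[DFSEdge, list[tuple[int, ...]]] = {}
        for emb in embs:
            for ext, new_emb in _embedding_extensions(
                tuple(code), rm_path, code_edges, labels, emb, graph
            ):
                lst = candidates.setdefault(ext, [])
                if new_emb not in lst:
                    lst.append(new_emb)
        ext = min(candidates, key=_ext_key)
        code.append(ext)
        embs = candidates[ext]
    return tuple(code)


def is_minimum_dfs_code(code: DFSCode) -> bool:
    """True iff ``code`` is the canonical (minimum) DFS code of its graph."""
    graph = code_to_graph(code)
    return min_dfs_code(graph) == tuple(code)


# ---------------------------------------------------------------------------
# frequent-pattern walk


@dataclass
class WalkStats:
    """Counters accumulated during a code-tree walk."""

    visited: int = 0  # minimal frequent patterns handed to the visitor
    pruned_by_visitor: int = 0  # subtrees the visitor declined to expand
    infrequent_extensions: int = 0  # children dropped by the support threshold
    nonminimal_skipped: int = 0  # children whose code is not canonical


def support_threshold(n: int, min_sup: float | None, min_sup_count: int | None) -> int:
    if min_sup_count is not None:
        if not 1 <= min_sup_count <= n:
            raise ValueError("min_sup_count must be in [1, n]")
        return int(min_sup_count)
    if min_sup is None or not 0 < min_sup <= 1:
        raise ValueError("min_sup must be a fraction in (0, 1]")
    return max(1, math.ceil(min_sup * n))


def dfs_walk(
    dataset: GraphDataset,
    min_sup: float | None = None,
    *,
    min_sup_count: int | None = None,
    max_edges: int | None = None,
    include_singletons: bool = True,
    visitor: Callable[[SubgraphPattern, Embeddings], bool] | None = None,
    stats: WalkStats | None = None,
) -> WalkStats:
    """Depth-first walk of the canonical frequent-pattern tree.

    ``visitor(pattern, embeddings)`` is called on every minimal frequent
    pattern in canonical depth-first order and returns True to expand the
    pattern's subtree, False to prune it.  Frequency pruning (support
    anti-monotonicity) is always applied.
    """
    n = len(dataset)
    thresh = support_threshold(n, min_sup, min_sup_count)
    stats = stats if stats is not None else WalkStats()
    visitor = visitor if visitor is not None else (lambda p, e: True)
    graphs = dataset.graphs

    def visit(pattern: SubgraphPattern, embeddings: Embeddings) -> bool:
        stats.visited += 1
        expand = visitor(pattern, embeddings)
        if not expand:
            stats.pruned_by_visitor += 1
        return expand

    def recurse(code: DFSCode, embeddings: Embeddings) -> None:
        if max_edges is not None and len(code) >= max_edges:
            return
        for child_code, child_embs in rightmost_extensions(code, embeddings, dataset):
            if len(child_embs) < thresh:
                stats.infrequent_extensions += 1
                continue
            if not is_minimum_dfs_code(child_code):
                stats.nonminimal_skipped += 1
                continue
            pattern = SubgraphPattern(
                graph=code_to_graph(child_code),
                support=tuple(sorted(child_embs)),
                n=n,
                code=child_code,
            )
            if visit(pattern, child_embs):
                recurse(child_code, child_embs)

    # roots: single vertex labels in sorted order
    by_label: dict[int, Embeddings] = {}
    for gi, g in enumerate(graphs):
        for v, lab in g.labels.items():
            by_label.setdefault(lab, {}).setdefault(gi, []).append((v,))

    # one-edge minimal codes grouped by their root (smaller-endpoint) label
    def edge_children(label: int, embeddings: Embeddings) -> None:
        grouped: dict[DFSEdge, Embeddings] = {}
        for gi, embs in embeddings.items():
            host = graphs[gi]
            for (v,) in embs:
                for w, le in host.adj[v].items():
                    ext = (0, 1, label, le, host.labels[w])
                    grouped.setdefault(ext, {}).setdefault(gi, []).append((v, w))
        for ext in sorted(grouped, key=_ext_key):
            child_embs = grouped[ext]
            if len(child_embs) < thresh:
                stats.infrequent_extensions += 1
                continue
            code = (ext,)
            if not is_minimum_dfs_code(code):
                stats.nonminimal_skipped += 1
                continue
            pattern = SubgraphPattern(
                graph=code_to_graph(code),
                support=tuple(sorted(child_embs)),
                n=n,
                code=code,
            )
            if visit(pattern, child_embs) and (max_edges is None or max_edges > 1):
                recurse(code, child_embs)

    for label in sorted(by_label):
        embeddings = by_label[label]
        if len(embeddings) < thresh:
            stats.infrequent_extensions += 1
            continue
        if include_singletons:
            pattern = SubgraphPattern(
                graph=LabeledGraph([label]),
                support=tuple(sorted(embeddings)),
                n=n,
                code=None,
            )
            if not visit(pattern, embeddings):
                continue
        if max_edges is None or max_edges >= 1:
            edge_children(label, embeddings)
    return stats


def enumerate_frequent(
    dataset: GraphDataset,
    min_sup: float | None = None,
    *,
    min_sup_count: int | None = None,
    max_edges: int | None = None,
    include_singletons: bool = True,
) -> Iterator[SubgraphPattern]:
    """Yield every frequent connected pattern (one per isomorphism class).

    ``min_sup`` is a fraction of the dataset; a pattern is frequent when
    its support size is at least ``ceil(min_sup * n)``.  ``min_sup_count``
    overrides the threshold with an absolute count.
    """
    out: list[SubgraphPattern] = []

    def collect(pattern: SubgraphPattern, _embs: Embeddings) -> bool:
        out.append(pattern)
        return True

    dfs_walk(
        dataset,
        min_sup,
        min_sup_count=min_sup_count,
        max_edges=max_edges,
        include_singletons=include_singletons,
        visitor=collect,
    )
    yield from out
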