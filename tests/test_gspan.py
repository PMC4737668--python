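"""Canonical DFS-code enumeration against brute-force oracles."""

import numpy as np
import pytest

from gmsv.graph_core import GraphDataset, LabeledGraph, compute_support
from gmsv.gspan import (
    code_to_graph,
    dfs_walk,
    enumerate_frequent,
    is_minimum_dfs_code,
    min_dfs_code,
    rightmost_extensions,
)

from conftest import lattice_frequent, nx_isomorphic, random_small_dataset


def all_dfs_codes(graph: LabeledGraph):
    """Brute-force generator of every full DFS code of a graph.

    Independent re-derivation from the definition: grow codes one edge at
    a time, allowing backward edges from the rightmost vertex to the
    rightmost path and forward edges from any rightmost-path vertex.
    """
    n_edges = graph.n_edges
    out = []

    def rightmost_path(code):
        parent = {}
        top = 0
        for i, j, *_ in code:
            if j > i:
                parent[j] = i
                top = max(top, j)
        path = [top]
        while path[-1] != 0:
            path.append(parent[path[-1]])
        return path[::-1]

    def grow(code, mapping):  # mapping: dfs index -> graph vertex
        if len(code) == n_edges:
            out.append(tuple(code))
            return
        used = {(min(i, j), max(i, j)) for i, j, *_ in code}
        path = rightmost_path(code)
        vr = path[-1]
        inv = set(mapping.values())
        for v in path[:-1]:  # backward
            if (min(v, vr), max(v, vr)) in used:
                continue
            le = graph.adj[mapping[vr]].get(mapping[v])
            if le is not None:
                grow(
                    code + [(vr, v, graph.labels[mapping[vr]], le, graph.labels[mapping[v]])],
                    mapping,
                )
        new = len(mapping)
        for v in path:  # forward
            for w, le in graph.adj[mapping[v]].items():
                if w in inv:
                    continue
                grow(
                    code + [(v, new, graph.labels[mapping[v]], le, graph.labels[w])],
                    {**mapping, new: w},
                )

    for u in graph.labels:
        for v, le in graph.adj[u].items():
            grow([(0, 1, graph.labels[u], le, graph.labels[v])], {0: u, 1: v})
    return out


class TestMinimality:
    def test_single_edge_orientations(self):
        assert is_minimum_dfs_code(((0, 1, 1, 0, 2),))
        assert not is_minimum_dfs_code(((0, 1, 2, 0, 1),))
        assert is_minimum_dfs_code(((0, 1, 3, 0, 3),))

    def test_malformed_codes_rejected(self):
        with pytest.raises(ValueError):
            is_minimum_dfs_code(())
        with pytest.raises(ValueError):
            is_minimum_dfs_code(((1, 2, 0, 0, 0),))
        with pytest.raises(ValueError):
            is_minimum_dfs_code(((0, 1, 1, 0, 2), (0, 3, 1, 0, 2)))

    def test_uniform_triangle_has_exactly_one_minimal_code(self):
        tri = LabeledGraph([1, 1, 1], [(0, 1), (1, 2), (0, 2)])
        codes = set(all_dfs_codes(tri))
        minimal = [c for c in codes if is_minimum_dfs_code(c)]
        assert len(minimal) == 1
        assert min_dfs_code(tri) == minimal[0]

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_min_code_is_the_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed)
        nv = int(rng.integers(3, 6))
        # random spanning tree plus a few extra edges: connected by design
        edges = {(int(rng.integers(0, v)), v) for v in range(1, nv)}
        extra = [(u, v) for u in range(nv) for v in range(u + 1, nv) if (u, v) not in edges]
        rng.shuffle(extra)
        edges.update(extra[: int(rng.integers(0, 3))])
        g = LabeledGraph(list(rng.integers(0, 3, size=nv)), sorted(edges))
        codes = all_dfs_codes(g)
        minimal = [c for c in codes if is_minimum_dfs_code(c)]
        assert len(set(minimal)) == 1
        assert min_dfs_code(g) in codes
        assert min_dfs_code(g) == minimal[0]
        assert nx_isomorphic(code_to_graph(min_dfs_code(g)), g)


class TestRightmostExtensions:
    def test_saturated_pattern_has_no_extensions(self):
        g = LabeledGraph([1, 2], [(0, 1)])
        ds = GraphDataset([g, g], np.array([1, -1]))
        code = ((0, 1, 1, 0, 2),)
        embeddings = {0: [(0, 1)], 1: [(0, 1)]}
        assert rightmost_extensions(code, embeddings, ds) == []

    def test_extensions_of_path_in_labeled_cycle_match_oracle(self):
        cycle = LabeledGraph([1, 2, 1, 2], [(0, 1), (1, 2), (2, 3), (3, 0)])
        ds = GraphDataset([cycle], np.array([1]))
        code = ((0, 1, 1, 0, 2),)
        embeddings = {0: [(0, 1), (0, 3), (2, 1), (2, 3)]}
        children = rightmost_extensions(code, embeddings, ds)
        # every child's support must equal the oracle-computed support
        for child_code, child_embs in children:
            pattern = code_to_graph(child_code)
            oracle = compute_support(pattern, ds)
            assert tuple(sorted(child_embs)) == oracle.support
        # the only one-edge supergraphs of edge(1,2) realized in a 4-cycle
        # are the two orientations of the path 1-2-1 / 2-1-2
        child_graphs = [code_to_graph(c) for c, _ in children]
        path121 = LabeledGraph([1, 2, 1], [(0, 1), (1, 2)])
        path212 = LabeledGraph([2, 1, 2], [(0, 1), (1, 2)])
        assert any(nx_isomorphic(g, path121) for g in child_graphs)
        assert any(nx_isomorphic(g, path212) for g in child_graphs)
        assert len(children) == 2

    def test_child_supports_are_subsets_of_parent(self):
        rng = np.random.default_rng(11)
        ds, _ = random_small_dataset(rng, n=10, max_nodes=6, max_edges=8)
        seen = {}

        def visitor(pattern, embeddings):
            if pattern.code is not None:
                parent = pattern.code[:-1]
                if parent:
                    assert set(pattern.support) <= set(seen[parent])
                seen[pattern.code] = pattern.support
            return True

        dfs_walk(ds, 0.2, visitor=visitor)
        assert seen  # walked something


class TestEnumeration:
    def test_three_identical_edge_graphs(self, toy_edge_dataset):
        pats = list(enumerate_frequent(toy_edge_dataset, 1.0))
        keys = sorted(
            (p.graph.n_edges, tuple(sorted(p.graph.labels.values()))) for p in pats
        )
        assert keys == [(0, (1,)), (0, (2,)), (1, (1, 2))]
        assert all(p.support == (0, 1, 2) for p in pats)

    def test_infrequent_label_filtered(self):
        ds = GraphDataset(
            [LabeledGraph([1, 9], [(0, 1)]), LabeledGraph([1, 2], [(0, 1)]),
             LabeledGraph([1, 2], [(0, 1)])],
            np.array([1, -1, 1]),
        )
        labels = {
            tuple(sorted(p.graph.labels.values()))
            for p in enumerate_frequent(ds, 2 / 3)
            if p.graph.n_edges == 0
        }
        assert (9,) not in labels
        assert (1,) in labels and (2,) in labels

    def test_min_sup_validation(self, toy_edge_dataset):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                list(enumerate_frequent(toy_edge_dataset, bad))

    def test_max_edges_cap_and_singleton_exclusion(self, toy_edge_dataset):
        no_singles = list(
            enumerate_frequent(toy_edge_dataset, 1.0, include_singletons=False)
        )
        assert all(p.graph.n_edges >= 1 for p in no_singles)
        capped = list(enumerate_frequent(toy_edge_dataset, 1.0, max_edges=0))
        assert all(p.graph.n_edges == 0 for p in capped)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_lattice(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds, _ = random_small_dataset(rng, n=5, max_nodes=6, max_edges=8)
        thresh = 2  # 0.4 of 5
        mined = list(enumerate_frequent(ds, 0.4))
        oracle = lattice_frequent(ds, thresh)
        assert len(mined) == len(oracle)
        # canonical uniqueness: no two mined patterns isomorphic
        for i in range(len(mined)):
            for j in range(i + 1, len(mined)):
                assert not nx_isomorphic(mined[i].graph, mined[j].graph)
        # 1-1 match with identical supports
        unmatched = list(oracle)
        for p in mined:
            hit = next(
                (o for o in unmatched
                 if o[1] == p.support and nx_isomorphic(o[0], p.graph)),
                None,
            )
            assert hit is not None, f"pattern {p.graph} not found in oracle lattice"
            unmatched.remove(hit)
        assert not unmatched
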