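"""Reading brain-network inputs and writing mined patterns.

Connectivity comes in as one square CSV/TSV weight matrix per subject
(rows/columns = atlas regions), bound together by a manifest CSV with
columns ``subject_id, path, label``.  Weighted matrices are thresholded
into binary undirected graphs whose vertex labels are the region indices;
only positive weights can become links.  Side views and labels are plain
CSV tables aligned to subjects by ID.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import GraphDataset, LabeledGraph
from .side_views import SideView

__all__ = [
    "ConnectivityMatrix",
    "read_connectivity_matrix",
    "normalize_link_weights",
    "threshold_to_graph",
    "load_dataset",
    "load_side_view",
    "load_labels",
    "pattern_to_dict",
    "pattern_from_dict",
    "write_patterns_json",
    "read_patterns_json",
    "pattern_to_graphml",
]

_SYM_TOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """A subject's square, symmetric region-by-region weight matrix."""

    weights: np.ndarray
    region_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {w.shape}")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > _SYM_TOL:
            warnings.warn(
                f"asymmetric connectivity (max |w - wᵀ| = {asym:.3g}); "
                "symmetrizing by averaging",
                stacklevel=2,
            )
        self.weights = (w + w.T) / 2.0
        if not self.region_names:
            self.region_names = [str(i) for i in range(w.shape[0])]
        if len(self.region_names) != w.shape[0]:
            raise ValueError("one region name per row required")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _looks_numeric(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_connectivity_matrix(path: str | Path, subject_id: str = "") -> ConnectivityMatrix:
    """Parse a square CSV/TSV weight matrix, with optional region header."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    has_header = not all(_looks_numeric(c) for c in rows[0][1:] + rows[0][:1])
    names: list[str] = []
    if has_header:
        header = rows[0]
        body = rows[1:]
        # header row may start with an empty corner cell
        first_col_named = body and not _looks_numeric(body[0][0])
        names = header[1:] if (len(header) == len(body[0]) and first_col_named) else header
        names = [c.strip() for c in names if c.strip()] or names
        if body and not _looks_numeric(body[0][0]):
            body = [r[1:] for r in body]
    else:
        body = rows
    try:
        w = np.array([[float(c) for c in r] for r in body], dtype=float)
    except ValueError as exc:
        for ri, r in enumerate(body):
            for ci, c in enumerate(r):
                if not _looks_numeric(c):
                    raise ValueError(
                        f"{path}: non-numeric value {c!r} at row {ri}, column {ci}"
                    ) from exc
        raise
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {w.shape}")
    if names and len(names) != w.shape[0]:
        names = []
    return ConnectivityMatrix(
        weights=w, region_names=names, subject_id=subject_id or path.stem
    )


def normalize_link_weights(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Min-max rescale off-diagonal weights to [0, 1] over the whole matrix."""
    w = matrix.weights.copy()
    m = w.shape[0]
    off = ~np.eye(m, dtype=bool)
    vals = w[off]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("cannot min-max normalize: all off-diagonal weights equal")
    w[off] = (vals - lo) / (hi - lo)
    return ConnectivityMatrix(
        weights=w, region_names=list(matrix.region_names), subject_id=matrix.subject_id
    )


def threshold_to_graph(
    matrix: ConnectivityMatrix, threshold: float, *, strict: bool = True
) -> LabeledGraph:
    """Binary undirected graph from a weight matrix.

    An edge (u, v) is present iff w_uv > threshold (``strict=False``
    switches to ≥).  Negative weights never become links regardless of the
    threshold sign (positive-correlation convention).  Vertex labels are
    the region indices; isolated vertices are retained.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    m = matrix.n_regions
    w = matrix.weights
    edges = []
    for u in range(m):
        for v in range(u + 1, m):
            keep = w[u, v] > threshold if strict else w[u, v] >= threshold
            if keep and w[u, v] > 0:
                edges.append((u, v))
    return LabeledGraph(list(range(m)), edges)


def load_dataset(
    manifest_path: str | Path,
    threshold: float,
    *,
    strict: bool = True,
    normalize: bool = False,
) -> GraphDataset:
    """Build a GraphDataset from a manifest CSV (subject_id, path, label).

    Paths are resolved relative to the manifest's directory; manifest row
    order fixes the subject order everywhere downstream.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    graphs, labels, ids = [], [], []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        mat = read_connectivity_matrix(manifest_path.parent / str(row["path"]), sid)
        if normalize:
            mat = normalize_link_weights(mat)
        graphs.append(threshold_to_graph(mat, threshold, strict=strict))
        labels.append(int(row["label"]))
        ids.append(sid)
    return GraphDataset(graphs=graphs, labels=np.array(labels), ids=ids)


def load_side_view(
    path: str | Path,
    ids: list[str],
    *,
    weight: float = 1.0,
    id_column: str | None = None,
    strict: bool = True,
) -> SideView:
    """Load one side view CSV (subject-ID column + numeric measures).

    Rows are re-ordered to match ``ids``.  In strict mode every dataset
    subject must appear exactly once.
    """
    path = Path(path)
    table = pd.read_csv(path)
    id_col = id_column or table.columns[0]
    table[id_col] = table[id_col].astype(str)
    if table[id_col].duplicated().any():
        raise ValueError(f"{path}: duplicate subject IDs")
    missing = [s for s in ids if s not in set(table[id_col])]
    if missing:
        if strict:
            raise ValueError(f"{path}: missing subjects {missing}")
        ids = [s for s in ids if s not in missing]
    table = table.set_index(id_col).loc[[str(s) for s in ids]]
    feats = table.to_numpy(dtype=float)
    return SideView(
        features=feats,
        weight=weight,
        name=path.stem,
        column_names=list(table.columns),
    )


def load_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Two-column CSV (subject_id, label ∈ {−1, +1}) → (ids, labels)."""
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected subject_id and label columns")
    ids = [str(s) for s in table.iloc[:, 0]]
    labels = table.iloc[:, 1].to_numpy(dtype=int)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError(f"{path}: labels must be -1 or +1")
    return ids, labels


# ---------------------------------------------------------------------------
# pattern serialization


def pattern_to_dict(graph: LabeledGraph, **extra) -> dict:
    """JSON-ready representation: vertex labels and label-pair edge list."""
    verts = sorted(graph.labels)
    d = {
        "node_labels": [graph.labels[v] for v in verts],
        "edges": [
            [graph.labels[u], graph.labels[v], le] for u, v, le in sorted(graph.edges())
        ],
    }
    d.update(extra)
    return d


def pattern_from_dict(d: dict) -> LabeledGraph:
    """Rebuild a pattern graph from its serialized form (up to isomorphism).

    Vertices are reconstructed from the node-label list; edges reference
    labels, which is unambiguous for the region-labeled graphs this
    package serializes (each label occurs once).  Repeated labels with
    edges would be ambiguous and are rejected.
    """
    labels = [int(x) for x in d["node_labels"]]
    edges = d.get("edges", [])
    if edges and len(set(labels)) != len(labels):
        raise ValueError("cannot rebuild edges of a pattern with repeated node labels")
    by_label = {lab: i for i, lab in enumerate(labels)}
    return LabeledGraph(
        labels, [(by_label[int(a)], by_label[int(b)], int(le)) for a, b, le in edges]
    )


def write_patterns_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_patterns_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def pattern_to_graphml(graph: LabeledGraph, path: str | Path) -> None:
    """Optional GraphML export for external viewers."""
    import networkx as nx

    g = nx.Graph()
    for v, lab in graph.labels.items():
        g.add_node(v, label=int(lab))
    for u, v, le in graph.edges():
        g.add_edge(u, v, label=int(le))
    nx.write_graphml(g, str(path))
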