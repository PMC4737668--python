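"""Seeded synthetic datasets with planted discriminative subgraphs.

The generator emulates the shape of a small case/control brain-network
study: tens of subjects, a fixed vocabulary of ~90 atlas regions (vertex
labels, unique per graph), sparse background connectivity, a small
"planted" subgraph whose presence probability depends on the class, and
one or more vector side views whose class means are separated by a
controllable gap so that within-class kernel similarity exceeds
between-class similarity.

Everything is driven by a single integer seed; identical configurations
produce identical datasets (and, via :func:`write_fixture`, byte-identical
files).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .graph_core import GraphDataset, LabeledGraph, compute_support
from .side_views import SideView

__all__ = [
    "ViewSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_planted_pattern",
    "sample_views",
    "generate_dataset",
    "write_fixture",
]


@dataclass(frozen=True)
class ViewSpec:
    """One synthetic side view: dimensionality, class-mean gap, noise scale.

    ``class_gap`` is the Euclidean distance between the two class mean
    vectors in units of the within-class standard deviation (the gap is
    spread evenly across dimensions).  Gap 0 yields label-independent
    features (the null of the consistency test).
    """

    dim: int = 10
    class_gap: float = 1.0
    noise_sd: float = 1.0


def default_planted_pattern() -> LabeledGraph:
    """A 3-edge triangle over three fixed region labels."""
    return LabeledGraph({0: 10, 1: 35, 2: 60}, [(0, 1), (1, 2), (0, 2)])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a modest case/control imaging study: 20+20 subjects,
    90 labeled regions, ~10% background link density, a triangle pattern
    strongly enriched in the positive class, and two side views of
    heterogeneous label consistency (a stronger 10-dim panel and a weaker
    5-dim one).
    """

    n_pos: int = 20
    n_neg: int = 20
    n_nodes: int = 90
    edge_density: float = 0.1
    planted_pattern: LabeledGraph = field(default_factory=default_planted_pattern)
    p_present_pos: float = 0.9
    p_present_neg: float = 0.1
    views: list[ViewSpec] = field(
        default_factory=lambda: [ViewSpec(10, 1.0, 1.0), ViewSpec(5, 0.5, 1.0)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg < 2:
            raise ValueError("need at least two subjects")
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        for p in (self.p_present_pos, self.p_present_neg):
            if not 0 <= p <= 1:
                raise ValueError("presence probabilities must be in [0, 1]")
        bad = [l for l in self.planted_pattern.labels.values() if not 0 <= l < self.n_nodes]
        if bad:
            raise ValueError(
                f"planted pattern uses labels {bad} outside the node vocabulary "
                f"0..{self.n_nodes - 1}"
            )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Bookkeeping of every class-dependent draw the generator made."""

    planted_pattern: LabeledGraph
    forced_present: np.ndarray  # bool per subject: planted edges were injected
    realized_support: tuple[int, ...]  # graphs actually containing the pattern
    view_means: list[np.ndarray]  # per view: (2, d) array of class means (+1 row 0)


def sample_views(
    labels: np.ndarray, specs: list[ViewSpec], rng: np.random.Generator
) -> tuple[list[SideView], list[np.ndarray]]:
    """Draw class-conditional Gaussian features for each view spec."""
    y = np.asarray(labels)
    n = y.size
    views, means = [], []
    for vi, spec in enumerate(specs):
        u = np.ones(spec.dim) / np.sqrt(spec.dim)
        mu_pos = (spec.class_gap / 2.0) * spec.noise_sd * u
        mu_neg = -mu_pos
        feats = rng.normal(0.0, spec.noise_sd, size=(n, spec.dim))
        feats[y > 0] += mu_pos
        feats[y < 0] += mu_neg
        views.append(SideView(feats, weight=1.0, name=f"view{vi}"))
        means.append(np.vstack([mu_pos, mu_neg]))
    return views, means


def generate_dataset(
    config: SimulationConfig,
) -> tuple[GraphDataset, list[SideView], GroundTruth]:
    """One synthetic dataset: graphs, side views, and ground truth.

    Per subject a background Erdős–Rényi graph on the labeled node set is
    sampled at ``edge_density``; with class-conditional probability the
    planted pattern's edges are then OR-ed in.  Positive subjects come
    first in the dataset order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    labels = np.concatenate([np.ones(config.n_pos, int), -np.ones(config.n_neg, int)])
    m = config.n_nodes
    iu, ju = np.triu_indices(m, k=1)
    planted_edges = [
        (
            config.planted_pattern.labels[u],
            config.planted_pattern.labels[v],
        )
        for u, v, _ in config.planted_pattern.edges()
    ]
    graphs: list[LabeledGraph] = []
    forced = np.zeros(n, dtype=bool)
    for s in range(n):
        present = rng.random((iu.size,)) < config.edge_density
        p_inject = config.p_present_pos if labels[s] > 0 else config.p_present_neg
        forced[s] = rng.random() < p_inject
        edges = {(int(a), int(b)) for a, b in zip(iu[present], ju[present])}
        if forced[s]:
            edges.update((min(a, b), max(a, b)) for a, b in planted_edges)
        graphs.append(LabeledGraph(list(range(m)), sorted(edges)))
    ids = [f"s{j:03d}" for j in range(n)]
    dataset = GraphDataset(graphs=graphs, labels=labels, ids=ids)
    views, means = sample_views(labels, config.views, rng)
    realized = compute_support(config.planted_pattern, dataset).support
    truth = GroundTruth(
        planted_pattern=config.planted_pattern,
        forced_present=forced,
        realized_support=realized,
        view_means=means,
    )
    return dataset, views, truth


# ---------------------------------------------------------------------------
# fixture export (exercises the full file-based pipeline)


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def write_fixture(
    dataset: GraphDataset, views: list[SideView], out_dir: str | Path
) -> Path:
    """Write the dataset as the file layout the IO layer consumes.

    Per-subject connectivity CSVs carry weight 1.0 for present edges and
    0.0 otherwise, so any threshold in (0, 1) reproduces the graphs
    exactly.  Returns the manifest path.  Output is byte-deterministic
    for a given dataset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "matrices").mkdir(exist_ok=True)
    manifest_rows = []
    for j, (sid, graph) in enumerate(zip(dataset.ids, dataset.graphs)):
        m = graph.n_vertices
        w = np.zeros((m, m))
        for u, v, _ in graph.edges():
            w[u, v] = w[v, u] = 1.0
        rel = f"matrices/{sid}.csv"
        with open(out / rel, "w", newline="\n") as fh:
            fh.write(",".join(f"r{i}" for i in range(m)) + "\n")
            for row in w:
                fh.write(",".join(_fmt(x) for x in row) + "\n")
        manifest_rows.append((sid, rel, int(dataset.labels[j])))
    for vi, view in enumerate(views):
        name = view.name or f"view{vi}"
        with open(out / f"{name}.csv", "w", newline="\n") as fh:
            cols = view.column_names or [f"f{c}" for c in range(view.d)]
            fh.write("subject_id," + ",".join(cols) + "\n")
            for sid, row in zip(dataset.ids, view.features):
                fh.write(sid + "," + ",".join(_fmt(x) for x in row) + "\n")
    with open(out / "labels.csv", "w", newline="\n") as fh:
        fh.write("subject_id,label\n")
        for sid, _, lab in manifest_rows:
            fh.write(f"{sid},{lab}\n")
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="\n") as fh:
        fh.write("subject_id,path,label\n")
        for sid, rel, lab in manifest_rows:
            fh.write(f"{sid},{rel},{lab}\n")
    return manifest
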