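# Methods

## Model

Each subject j is an undirected simple graph G_j with integer vertex
labels (for brain networks, the atlas region index — unique per graph,
though the isomorphism machinery handles repeated labels) and an
optional integer edge label (constant 0 throughout the brain-network
path). A pattern g is a connected labeled graph; g ⊆ G_j means there is
an injective, label-preserving map carrying every pattern edge to a host
edge (non-induced containment). The occurrence vector f of g has
f_j = 1 iff g ⊆ G_j; the support set is {j : f_j = 1}. Supports are
anti-monotone: extending a pattern can only shrink its support.

### Guidance construction

Each side view is an n×d feature table. Features are min-max normalized
per column (constant columns map to 0), then summarized by the RBF
kernel κ_ij = exp(−‖z_i − z_j‖²/d) with bandwidth equal to the view's
dimensionality, so per-coordinate noise contributes on a comparable
scale for panels of any width.

Per view, Θ_ij = 1/|H| if κ_ij ≥ μ and −1/|L| if κ_ij < μ, where μ is
the mean of **all n² kernel entries including the diagonal** and H/L are
the at-or-above/below-mean pair sets. Taking μ over all entries (and
letting diagonal pairs land in H) follows the criterion's definition
literally; it is harmless because the diagonal of Φ provably cannot
change any score (the (f_i − f_i)² terms of the quadratic form vanish —
unit-tested). Ties κ_ij = μ go to H. The ±1/|set| normalization makes
the entries over H sum to +1 and over L to −1, balancing the pull of
similar and dissimilar pairs. A kernel with an empty H or L (constant
view) is rejected as degenerate.

Labels y ∈ {−1, +1} (0 = unlabeled) yield Ω_ij = 1/|M| for same-label
ordered pairs (diagonal included), −1/|C| for different-label pairs, and
0 when either subject is unlabeled. A labeled single-class dataset is an
error; a fully unlabeled dataset yields Ω = 0 (the guidance must then
come from views; an all-zero Φ is rejected).

Φ = Ω + Σ_p λ_p Θ_p with per-view weights λ_p ≥ 0 (default 1, treating
views symmetrically; weight learning is out of scope). L = D − Φ with
D = diag(row sums of Φ). Because Φ has mixed signs, L is a **signed**
Laplacian: its rows sum to zero and fᵀLf = ½ ΣΦ_ij(f_i − f_j)², but it
need not be positive semi-definite, so pattern scores can be negative.
Nothing in the package assumes q ≥ 0.

### Score and bound

q(g) = fᵀLf, computed as the sum of L over support pairs
(O(|support|²), equivalent to the dense form — unit-tested). Lower is
better. With L̂ = min(0, L) elementwise, q̂(g) = fᵀL̂f satisfies
q̂(g) ≤ q(g′) for every supergraph g′ of g: the support of g′ is a
subset of g's, every L̂ entry is ≤ 0 (dropping pairs cannot lower the
sum) and ≤ L (entrywise). Scores depend on a pattern only through its
support set.

### Search

Patterns are enumerated by gSpan DFS codes: ordered edge tuples
(i, j, l_i, l_e, l_j) grown by rightmost-path extension, with the
lexicographic-minimum code as canonical form (one tree node per
isomorphism class). Minimality is checked by greedily rebuilding the
minimum code of the decoded pattern; non-minimal codes are neither
scored nor extended. Extension order is the standard one: backward
before forward, smaller backward target first, deeper forward origin
first, then labels. Frequency uses threshold ⌈min_sup · n⌉ (an absolute
count override exists). Single-vertex patterns are enumerated and
scorable by default — they are valid features — and can be excluded by
flag. Support is counted by embedding lists (all injective occurrences
per graph), exact at the tool's intended scale of tens of graphs;
the brute-force isomorphism oracle is reserved for feature recomputation
on held-out graphs and for tests.

The top-k container keeps the k lowest (q, canonical-code) pairs; ties
in q break toward the lexicographically smaller code, making results
traversal-order independent. θ is the worst kept q once the container is
full (+∞ before that, so no pruning can occur while the container could
still absorb anything). Every visited pattern is scored *before* its
subtree is tested for pruning, since the bound governs descendants only.
Pruning uses exact ≥ on computed doubles: an epsilon slack could only
weaken pruning, never correctness, because the true bound is ≤ the
score. The unpruned mode differs only in skipping the bound test and is
the reference in equivalence tests; the explored-pattern counter is the
pruning-effectiveness metric (no wall-clock assertions — hardware-
dependent).

### Consistency test

Over unordered pairs i < j (the diagonal κ_ii = 1 would only dilute both
groups; ordered duplicates would double-count — a documented
interpretation), kernel values split into same-label A_s and
different-label A_d. Equal-size samples (size min(|A_s|, |A_d|) by
default) are drawn without replacement, seeded, and Welch's one-tailed
t-test evaluates H₀: μ_s − μ_d ≤ 0. Welch is the default because
nothing guarantees equal variances; a pooled-variance flag exists.
Kernel pairs sharing a subject are dependent, so the nominal level is
approximate; Monte-Carlo calibration (acceptance suite) shows the
realized 5%-level type-I rate ≈ 0.03 at n = 40 — slightly conservative,
not inflated.

## Synthetic data

The generator emulates the shape of a small case/control connectome
study, not its physiology: per subject an Erdős–Rényi background graph
on the labeled node set (default 90 nodes, density 0.1 ≈ a sparse
thresholded network), a planted triangle on three fixed regions OR-ed in
with class-conditional probability (default 0.9 positives / 0.1
negatives), and Gaussian side views whose class means are separated by
`class_gap` within-class SDs along a fixed unit direction (gap spread
across dimensions, so gap = ‖μ₊ − μ₋‖/σ). Defaults: 20+20 subjects, two
views (10-dim gap 1.0, 5-dim gap 0.5) — heterogeneous consistency, with
views informative but far from separating, leaving headroom for graph
features to help. What it does **not** model: correlated region
activity, geometric/community structure, heavy-tailed weights, view
collinearity, missing data. Passing tests therefore demonstrate
correctness and calibration of the machinery under controlled
conditions, not clinical performance.

`write_fixture` round-trips everything through the file formats (0/1
weight matrices so any threshold in (0,1) reproduces the graphs);
output is byte-deterministic and a 6-subject corpus (12 regions) is
committed for IO tests.

## Evaluation protocol

Balanced classes (seeded undersampling of the majority), stratified
3-fold CV, linear-kernel SVM at default regularization (C = 1), metrics
accuracy/precision/recall/F1 with +1 as the positive class. Default mode
re-mines patterns and rebuilds the guidance inside each training fold;
test-fold features are recomputed by containment checks, and view
normalization statistics are fit on training rows only (no leakage;
asserted by test). A global-mining variant exists for precomputed
feature matrices. Whether per-fold or global selection is "standard"
for this protocol family is genuinely open; per-fold is the default
because it is the honest estimate.

## Problem sizes and numerical conventions

Score comparisons in tests use 1e−9 tolerance. Exactness and
enumeration checks run on 20-graph datasets with ≤ 8 nodes / ≤ 10 edges
against a brute-force lattice (all connected edge subsets, VF2-
deduplicated, VF2-supported, densely scored); calibration uses 500/100
Monte-Carlo repetitions at n = 40; recovery and classification checks
use 20 seeds at the generator defaults; the pruning trend uses a denser
20-subject, 30-node dataset (density 0.25, k = 5) over min_sup
{0.6, 0.4, 0.3, 0.2}, where the bound's advantage grows as the frequent
set explodes. These sizes were chosen as the smallest instances that
exercise every code path convincingly.

## Known limitations

- The signed Laplacian breaks the q ≥ 0 intuition of classical
  (non-negative-affinity) Laplacian scores; only the quadratic-form
  identity is asserted, deliberately.
- Equal-q boundary ties between patterns with *different* supports could
  in principle make pruned and unpruned runs keep different tied
  patterns; with continuous side views such exact ties have measure
  zero, and all equivalence tests compare (q, support) pairs.
- The brute-force isomorphism oracle is exponential; it is applied only
  to small mined patterns against ≤ ~100-node hosts, where label
  filtering makes it effectively linear.
- Directed graphs, self-loops, multigraphs, weighted-edge isomorphism,
  view-weight learning, and diversity-adjusted selection are out of
  scope.
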