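"""The gSide evaluation criterion and its search lower bound.

gSide scores a subgraph pattern by the Laplacian quadratic form of its
binary occurrence vector f: q(g) = fᵀLf, which expands to the sum of
L_pq over all ordered pairs (p, q) of graphs in the pattern's support.
Lower is better: a low q means the pattern's presence/absence respects
the similarity structure of the side views and the class labels.

Because supports shrink along the pattern-extension tree (anti-
monotonicity) and L̂ = min(0, L) is elementwise ≤ L and ≤ 0, the quantity
q̂(g) = fᵀL̂f never exceeds q(g') for any supergraph g' of g.  This is
the bound that lets the miner discard whole subtrees.
"""

from __future__ import annotations

import numpy as np

from .graph_core import SubgraphPattern
from .side_views import GuidanceLaplacian

__all__ = ["gside_score", "gside_lower_bound", "support_score"]


def support_score(support: tuple[int, ...], matrix: np.ndarray, n: int) -> float:
    """Sum of matrix entries over ordered pairs drawn from ``support``.

    Equivalent to fᵀ·matrix·f for the indicator f of ``support`` but
    O(|support|²) instead of O(n²).
    """
    if support and (support[0] < 0 or support[-1] >= n):
        raise ValueError("support index out of range")
    if not support:
        return 0.0
    idx = np.asarray(support, dtype=int)
    return float(matrix[np.ix_(idx, idx)].sum())


def _check(pattern: SubgraphPattern, lap: GuidanceLaplacian) -> None:
    if pattern.n != lap.n:
        raise ValueError(
            f"pattern indicator length {pattern.n} does not match guidance size {lap.n}"
        )


def gside_score(pattern: SubgraphPattern, lap: GuidanceLaplacian) -> float:
    """q(g) = fᵀLf over the pattern's support pairs (lower is better)."""
    _check(pattern, lap)
    return support_score(pattern.support, lap.L, lap.n)


def gside_lower_bound(pattern: SubgraphPattern, lap: GuidanceLaplacian) -> float:
    """q̂(g) = fᵀL̂f — a lower bound on q of every supergraph of g."""
    _check(pattern, lap)
    return support_score(pattern.support, lap.L_hat, lap.n)
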