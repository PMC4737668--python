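"""Side views, kernels, guidance matrices, and the consistency test.

Each subject carries, besides its graph, one or more vector-valued "side
views" (e.g. clinical, immunologic, or cognitive measure panels).  A view
is summarized by an RBF kernel matrix over subjects; pairs more similar
than average pull their subgraph-feature representations together, pairs
less similar than average push them apart.  Together with same/different
class-label constraints this yields a signed affinity Φ and a Laplacian
L = D − Φ whose quadratic form fᵀLf scores a pattern's occurrence vector
f (see :mod:`gmsv.gside`).  The elementwise-clipped L̂ = min(0, L) drives
the branch-and-bound lower bound.

``consistency_test`` is a two-sample one-tailed t-test of whether
same-label subject pairs are more similar in a view's kernel than
different-label pairs — the property that justifies using the view to
guide subgraph selection at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "SideView",
    "KernelMatrix",
    "GuidanceLaplacian",
    "minmax_normalize",
    "rbf_kernel",
    "theta_matrix",
    "omega_matrix",
    "build_laplacian",
    "build_guidance",
    "consistency_test",
]


@dataclass
class SideView:
    """A per-subject feature table with a view weight.

    ``features`` is n×d with rows aligned to the dataset's subject order.
    ``weight`` (λ) scales this view's contribution to the guidance
    affinity; the default 1 treats all views equally.
    """

    features: np.ndarray
    weight: float = 1.0
    kernel_kind: str = "rbf"
    name: str = ""
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("side-view features must be an n×d matrix with d ≥ 1")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("side-view features contain non-finite values")
        if self.weight < 0:
            raise ValueError("view weight must be non-negative")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric similarity matrix κ with its grand mean μ (over all n² entries)."""

    kappa: np.ndarray
    mu: float


def minmax_normalize(features: np.ndarray) -> np.ndarray:
    """Rescale each column to [0, 1]; constant columns map to 0."""
    x = np.asarray(features, dtype=float)
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    out = np.zeros_like(x)
    nz = span > 0
    out[:, nz] = (x[:, nz] - lo[nz]) / span[nz]
    return out


def rbf_kernel(view: SideView) -> KernelMatrix:
    """RBF kernel κ_ij = exp(−‖z_i − z_j‖² / d), d = view dimensionality.

    The bandwidth is tied to the dimensionality so that per-coordinate
    noise contributes on a comparable scale regardless of panel size.
    """
    z = view.features
    sq = np.sum(z * z, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
    np.maximum(d2, 0.0, out=d2)
    kappa = np.exp(-d2 / view.d)
    kappa = (kappa + kappa.T) / 2.0
    return KernelMatrix(kappa=kappa, mu=float(kappa.mean()))


def theta_matrix(kernel: KernelMatrix) -> np.ndarray:
    """Signed, count-normalized similarity constraints from one kernel.

    Pairs at or above the kernel's grand mean form the "similar" set H and
    get weight 1/|H|; pairs below form the "dissimilar" set and get
    −1/|L|.  The normalization balances the total pull of the two sets
    (entries over H sum to +1, over L to −1).
    """
    kappa = kernel.kappa
    high = kappa >= kernel.mu
    n_high = int(high.sum())
    n_low = high.size - n_high
    if n_high == 0 or n_low == 0:
        raise ValueError(
            "degenerate side view: kernel is constant relative to its mean "
            "(all pairs similar or all dissimilar)"
        )
    theta = np.where(high, 1.0 / n_high, -1.0 / n_low)
    return theta


def omega_matrix(labels: np.ndarray) -> np.ndarray:
    """Signed, count-normalized label constraints over ordered subject pairs.

    Ω_ij = 1/|M| for same-label pairs, −1/|C| for different-label pairs,
    0 when either subject is unlabeled (label 0).  Counts are over ordered
    pairs including the diagonal.
    """
    y = np.asarray(labels, dtype=float).reshape(-1)
    yy = np.outer(y, y)
    same = yy > 0
    diff = yy < 0
    n_same = int(same.sum())
    n_diff = int(diff.sum())
    if not np.any(y != 0):
        return np.zeros((y.size, y.size))
    if n_same == 0 or n_diff == 0:
        raise ValueError("labels present but only one class: no between-class pairs")
    omega = np.zeros_like(yy)
    omega[same] = 1.0 / n_same
    omega[diff] = -1.0 / n_diff
    return omega


@dataclass
class GuidanceLaplacian:
    """The combined guidance affinity Φ and its (signed) Laplacians.

    Φ = Ω + Σ_p λ_p Θ_p; D = diag(row sums of Φ); L = D − Φ; and
    L̂ = min(0, L) elementwise.  Rows of L sum to zero, and L̂ ≤ L with
    L̂ ≤ 0 elementwise — the two facts behind the score lower bound.
    Because Φ mixes signs, L is a *signed* Laplacian and need not be
    positive semi-definite; nothing downstream assumes it is.
    """

    theta_list: list[np.ndarray]
    omega: np.ndarray
    phi: np.ndarray
    degree: np.ndarray
    L: np.ndarray
    L_hat: np.ndarray

    @property
    def n(self) -> int:
        return self.L.shape[0]


def build_laplacian(
    omega: np.ndarray,
    theta_list: list[np.ndarray] | None = None,
    weights: list[float] | np.ndarray | None = None,
) -> GuidanceLaplacian:
    """Combine label and per-view constraints into the guidance Laplacian."""
    omega = np.asarray(omega, dtype=float)
    n = omega.shape[0]
    if omega.shape != (n, n):
        raise ValueError("omega must be square")
    theta_list = [np.asarray(t, dtype=float) for t in (theta_list or [])]
    if weights is None:
        weights = [1.0] * len(theta_list)
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(theta_list):
        raise ValueError("one weight per theta matrix required")
    if np.any(weights < 0):
        raise ValueError("view weights must be non-negative")
    phi = omega.copy()
    for lam, theta in zip(weights, theta_list):
        if theta.shape != (n, n):
            raise ValueError("theta matrix shape mismatch")
        phi += lam * theta
    degree = phi.sum(axis=1)
    L = np.diag(degree) - phi
    L_hat = np.minimum(0.0, L)
    return GuidanceLaplacian(
        theta_list=theta_list,
        omega=omega,
        phi=phi,
        degree=degree,
        L=L,
        L_hat=L_hat,
    )


def build_guidance(
    labels: np.ndarray | None,
    views: list[SideView] | None,
    *,
    normalize: bool = True,
) -> GuidanceLaplacian:
    """End-to-end guidance construction from raw labels and side views.

    Applies min-max normalization and the RBF kernel per view, forms Θ per
    view and Ω from the labels, and combines them with the views' weights.
    Raises if the result carries no information at all (no labeled pairs
    and no effective views).
    """
    views = views or []
    n_candidates = [v.n for v in views]
    if labels is not None:
        n_candidates.append(np.asarray(labels).size)
    if not n_candidates:
        raise ValueError("need labels or at least one side view")
    n = n_candidates[0]
    if any(m != n for m in n_candidates):
        raise ValueError("labels and views disagree on the number of subjects")
    omega = (
        omega_matrix(labels) if labels is not None else np.zeros((n, n))
    )
    theta_list = []
    weights = []
    for view in views:
        feats = minmax_normalize(view.features) if normalize else view.features
        kern = rbf_kernel(SideView(feats, weight=view.weight, name=view.name))
        theta_list.append(theta_matrix(kern))
        weights.append(view.weight)
    lap = build_laplacian(omega, theta_list, weights)
    if not np.any(lap.phi):
        raise ValueError(
            "guidance is empty: no labeled pairs and all view weights are zero"
        )
    return lap


def _pair_values(kappa: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=float).reshape(-1)
    iu, ju = np.triu_indices(y.size, k=1)
    prod = y[iu] * y[ju]
    vals = kappa[iu, ju]
    return vals[prod > 0], vals[prod < 0]


def consistency_test(
    kernel: KernelMatrix,
    labels: np.ndarray,
    sample_size: int | None = None,
    seed: int | None = None,
    *,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample one-tailed t-test for side-information consistency.

    Over unordered subject pairs i < j, kernel similarities are split into
    same-label values A_s and different-label values A_d.  Equal-size
    samples (default size min(|A_s|, |A_d|)) are drawn without replacement
    with the given seed, and H₀: μ_s − μ_d ≤ 0 is tested against
    H₁: μ_s − μ_d > 0.  Welch's statistic by default; ``equal_var=True``
    switches to the pooled-variance form.

    Returns (t statistic, one-tailed p-value).
    """
    same, diff = _pair_values(kernel.kappa, labels)
    if same.size == 0 or diff.size == 0:
        raise ValueError("need at least one same-label and one different-label pair")
    size = min(same.size, diff.size) if sample_size is None else int(sample_size)
    if not 2 <= size <= min(same.size, diff.size):
        raise ValueError("sample size must be in [2, min(|A_s|, |A_d|)]")
    rng = np.random.default_rng(seed)
    a_s = rng.choice(same, size=size, replace=False)
    a_d = rng.choice(diff, size=size, replace=False)
    if np.array_equal(a_s, a_d) or (a_s.std() == 0 and a_d.std() == 0):
        # degenerate samples: identical groups carry no evidence either way
        return 0.0, 0.5
    res = sstats.ttest_ind(a_s, a_d, equal_var=equal_var, alternative="greater")
    return float(res.statistic), float(res.pvalue)
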