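"""Replicability analysis: partial-conjunction bounds and AdaFilter.

Given an m×v p-value matrix (rows = features, columns = independent studies),
the partial conjunction (PC) hypothesis H^{r/v} for a feature states that
fewer than r studies carry a true effect; rejecting it certifies replication
in at least r studies.  Testing H^{u/v} for increasing u by Fisher's
combination of the v−u+1 largest p-values inside closed testing yields, per
feature, a lower confidence bound d_i on the number of replicating studies:

    d_i = max{ r : p_i^{u/v} ≤ α/m  for all u = 0..r }.

Treating the m feature rows as disjoint focus sets, these are exactly the
per-focus partial closed-testing bounds at the Bonferroni level α/m (with the
Holm upgrade available when some feature reaches d_i = v).

AdaFilter is the fixed-r comparator: it filters PC hypotheses by
R_i = (v−r+1) p_{i(r−1)} and rejects when the selection p-value
S_i = (v−r+1) p_{i(r)} falls below the adaptive level
α̂ = sup{γ ∈ [0, α] : γ · #{R_i < γ} ≤ α}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .family import FeatureUniverse, FocusFamily
from .partial import FisherPartialOracle, holm_partial_bounds

__all__ = [
    "PValueMatrix",
    "ReplicabilityResult",
    "pc_pvalue",
    "pc_pvalues",
    "feature_bound",
    "feature_bounds",
    "adafilter",
    "adafilter_alpha_hat",
    "replicability_table",
]


@dataclass
class PValueMatrix:
    """m×v replicability p-values with cached per-row order statistics."""

    values: np.ndarray
    feature_ids: tuple = ()
    study_ids: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("p-value matrix must be 2-dimensional")
        if np.any(np.isnan(v)) or np.any(v < 0) or np.any(v > 1):
            raise ValueError("p-values must lie in [0, 1]")
        self.values = v
        if not self.feature_ids:
            self.feature_ids = tuple(f"feature_{i + 1}" for i in range(v.shape[0]))
        if not self.study_ids:
            self.study_ids = tuple(f"study_{j + 1}" for j in range(v.shape[1]))
        self._sorted = np.sort(v, axis=1)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]

    @property
    def sorted_rows(self) -> np.ndarray:
        """Per-row order statistics p_{i(1)} ≤ ... ≤ p_{i(v)}."""
        return self._sorted


@dataclass
class ReplicabilityResult:
    """Per-feature lower bounds on the number of replicating studies."""

    bounds: np.ndarray
    method_tag: str
    alpha: float
    r: int | None = None
    alpha_hat: float | None = None

    def mean_bound(self) -> float:
        return float(np.mean(self.bounds))


def _as_matrix(matrix) -> PValueMatrix:
    if isinstance(matrix, PValueMatrix):
        return matrix
    return PValueMatrix(np.asarray(matrix, dtype=float))


def pc_pvalue(row, r: int, floor: float = 1e-300) -> float:
    """Fisher PC p-value for H^{r/v}: combine the v−r+1 largest p-values.

    ``r = 0`` returns 0 by convention (H^{0/v} is always rejected).
    """
    p = np.sort(np.asarray(row, dtype=float))
    v = p.size
    if r > v:
        raise ValueError(f"r={r} exceeds the number of studies v={v}")
    if r == 0:
        return 0.0
    tail = np.maximum(p[r - 1 :], floor)
    stat = -2.0 * np.sum(np.log(tail))
    return float(stats.chi2.sf(stat, 2 * tail.size))


def pc_pvalues(matrix, floor: float = 1e-300) -> np.ndarray:
    """All Fisher PC p-values: out[i, r-1] tests H^{r/v} for feature i."""
    pm = _as_matrix(matrix)
    sp = np.maximum(pm.sorted_rows, floor)
    logs = np.log(sp)
    # suffix sums: stat[:, r-1] = -2 * sum_{j >= r} log p_(j)
    suffix = np.cumsum(logs[:, ::-1], axis=1)[:, ::-1]
    stats_mat = -2.0 * suffix
    dfs = 2 * np.arange(pm.v, 0, -1)
    return stats.chi2.sf(stats_mat, dfs[None, :])


def feature_bound(row, level: float) -> int:
    """d_i = max{r : PC p-value for H^{u/v} ≤ level for all u = 0..r}."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    p = np.asarray(row, dtype=float)
    d = 0
    for r in range(1, p.size + 1):
        if pc_pvalue(p, r) <= level:
            d = r
        else:
            break
    return d


def feature_bounds(matrix, level: float) -> np.ndarray:
    """Vectorised :func:`feature_bound` over every row of the matrix."""
    pc = pc_pvalues(matrix)
    ok = pc <= level
    # d_i = length of the leading run of rejections
    return np.cumprod(ok, axis=1).sum(axis=1).astype(np.int64)


def adafilter_alpha_hat(R: np.ndarray, alpha: float) -> float:
    """α̂ = sup{γ ∈ [0, α] : γ · #{R_i < γ} ≤ α}.

    The constraint function is piecewise linear with jumps only at the R_i,
    so the supremum is attained on the candidate grid
    {α} ∪ {α/k : k = 1..m} ∪ {R_i}, clipped to [0, α].
    """
    R = np.asarray(R, dtype=float)
    m = R.size
    candidates = np.concatenate(
        [[alpha], alpha / np.arange(1, m + 1), np.clip(R, 0.0, alpha)]
    )
    candidates = candidates[(candidates >= 0) & (candidates <= alpha)]
    counts = (R[None, :] < candidates[:, None]).sum(axis=1)
    feasible = candidates * counts <= alpha
    return float(candidates[feasible].max()) if feasible.any() else 0.0


def adafilter(matrix, r: int, alpha: float = 0.05) -> ReplicabilityResult:
    """AdaFilter-r: per-feature bound r if H^{r/v} rejected, else 0.

    Filtering p-value R_i = (v−r+1) p_{i(r−1)}, selection p-value
    S_i = (v−r+1) p_{i(r)}; rejection when S_i < α̂ (strict, as in the
    defining formulas).
    """
    pm = _as_matrix(matrix)
    v = pm.v
    if not (2 <= r <= v):
        raise ValueError(f"AdaFilter requires 2 <= r <= v, got r={r}, v={v}")
    sp = pm.sorted_rows
    R = (v - r + 1) * sp[:, r - 2]
    S = (v - r + 1) * sp[:, r - 1]
    alpha_hat = adafilter_alpha_hat(R, alpha)
    rejected = S < alpha_hat
    bounds = np.where(rejected, r, 0).astype(np.int64)
    return ReplicabilityResult(
        bounds=bounds,
        method_tag=f"adafilter-{r}",
        alpha=alpha,
        r=r,
        alpha_hat=alpha_hat,
    )


def replicability_table(
    matrix,
    alpha: float = 0.05,
    method: str = "partial_ct",
    r: int | None = None,
    holm: bool = False,
) -> ReplicabilityResult:
    """Per-feature replicating-study bounds by the requested method.

    ``partial_ct`` treats the m feature rows as disjoint focus sets and
    computes d_i = feature_bound(row, α/m) (Bonferroni over the partition);
    with ``holm=True`` the sequential alpha-recycling upgrade is applied, so
    features with all v studies certified release their share of alpha.
    ``adafilter`` requires ``r``.
    """
    pm = _as_matrix(matrix)
    if method == "adafilter":
        if r is None:
            raise ValueError("adafilter method requires r")
        return adafilter(pm, r, alpha)
    if method != "partial_ct":
        raise ValueError(f"unknown method {method!r}")
    m, v = pm.m, pm.v
    if not holm:
        bounds = feature_bounds(pm, alpha / m)
        return ReplicabilityResult(
            bounds=bounds, method_tag="partial_ct", alpha=alpha
        )
    # Holm upgrade through the generic combiner on the row partition
    universe = FeatureUniverse(range(m * v))
    members = tuple(
        frozenset(range(i * v, (i + 1) * v)) for i in range(m)
    )
    family = FocusFamily(universe, members)
    flat = pm.values.reshape(-1)
    oracles = [
        FisherPartialOracle(i, members[i], flat) for i in range(m)
    ]
    state = holm_partial_bounds(family, oracles, alpha)
    return ReplicabilityResult(
        bounds=np.asarray(state.bounds, dtype=np.int64),
        method_tag="partial_ct_holm",
        alpha=alpha,
    )
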