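"""Intersection-hypothesis (local) tests used inside closed testing.

Fisher's combination test is the default local test throughout: for k
p-values the statistic is -2 Σ log p_j, referred to a chi-square distribution
with 2k degrees of freedom.  Simes' test is provided as an alternative
reject/accept local test.  Both are exposed behind a common contract
``(p-values, level) -> reject?`` so the closed-testing machinery is
test-agnostic.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "fisher_pvalue",
    "fisher_reject",
    "simes_reject",
    "two_sample_t_pvalues",
    "PVALUE_FLOOR",
]

#: p-values of exactly zero are clamped here before taking logs
PVALUE_FLOOR = 1e-300


def _clean_pvalues(pvals, floor: float) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(
            f"p-value of 0 clamped to {floor:g} before log transform",
            RuntimeWarning,
            stacklevel=3,
        )
        p = np.maximum(p, floor)
    return p


def fisher_pvalue(pvals, floor: float = PVALUE_FLOOR) -> float:
    """Fisher combination p-value for the intersection of k hypotheses.

    Computed in log space: the statistic -2 Σ log p_j is compared to the
    chi-square survival function with 2k degrees of freedom.
    """
    p = _clean_pvalues(pvals, floor)
    stat = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(stat, 2 * p.size))


def fisher_reject(pvals, level: float, floor: float = PVALUE_FLOOR) -> bool:
    """Reject the intersection hypothesis by Fisher's combination at ``level``."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    return fisher_pvalue(pvals, floor=floor) <= level


def simes_reject(pvals, level: float) -> bool:
    """Simes test: reject iff min_j k p_(j) / j <= level."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value collection")
    k = p.size
    ranks = np.arange(1, k + 1)
    return bool(np.min(k * p / ranks) <= level)


def two_sample_t_pvalues(
    features: np.ndarray,
    response: np.ndarray,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Per-feature equal-variance two-sample t-test p-values.

    ``features`` is an n×w matrix (rows = samples, columns = features) and
    ``response`` a binary vector of length n splitting the samples into two
    groups.  Features with zero pooled variance get p = 1 with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(response)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("features must be n×w with response of length n")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError("response must contain exactly two groups")
    a = X[y == groups[0]]
    b = X[y == groups[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True, alternative=alternative)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero pooled variance; "
            "p-value set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(degenerate, 1.0, p)
    return p


def make_local_test(kind: str = "fisher") -> Callable[[Sequence[float], float], bool]:
    """Return a ``(p-values, level) -> reject?`` callable by name."""
    if kind == "fisher":
        return fisher_reject
    if kind == "simes":
        return simes_reject
    raise ValueError(f"unknown local test {kind!r}")
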