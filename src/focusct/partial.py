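"""Partial closed testing within one focus set.

A partial true-discovery guarantee procedure d_i^γ answers queries only for
subsets of its focus set F_i.  Here it is realised by closed testing over
2^{F_i} with a user-chosen local test.  Three evaluation routes exist:

* brute-force enumeration of all subsets of F_i (any local test, small sets);
* a fast sorted-suffix path for the full-set bound d_i^γ(F_i) under Fisher's
  combination (the only quantity the Holm/Bonferroni combiner needs);
* an exact size-stratified path for arbitrary query sets under Fisher, which
  scales to large universes and doubles as the full closed-testing comparator.

The module also implements the Bonferroni and Holm combinations that turn m
partial procedures into per-focus-set bounds at levels α/m resp. α/h.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .family import FocusFamily, HolmState, PartialBoundOracle, _round_level

__all__ = [
    "fisher_fullset_bound",
    "partial_bound_bruteforce",
    "fisher_subset_bound",
    "FisherPartialOracle",
    "bonferroni_partial_bounds",
    "holm_partial_bounds",
]

#: largest focus set for which subset queries are answered by enumeration
BRUTE_FORCE_CAP = 20


def _neg2logs(pvals, floor: float) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return -2.0 * np.log(np.maximum(p, floor))


def fisher_fullset_bound(pvals, level: float, floor: float = 1e-300) -> int:
    """Closed-testing bound d(F) for the full set under Fisher local tests.

    Among subsets of size k, the hardest to reject by Fisher is the one
    holding the k largest p-values; d(F) = |F| minus the largest k whose
    k-largest subset survives.  O(|F| log |F|).
    """
    terms = np.sort(_neg2logs(pvals, floor))  # ascending = largest p first
    n = terms.size
    # stat of the k largest p-values = sum of the k smallest terms
    cum = np.concatenate([[0.0], np.cumsum(terms)])
    ks = np.arange(n + 1)
    with np.errstate(over="ignore"):
        thresh = stats.chi2.isf(level, 2 * ks)
    thresh[0] = np.inf  # empty set is never rejected
    survivors = np.nonzero(cum < thresh)[0]
    return int(n - survivors.max())


def _fisher_rejection_table(
    terms: np.ndarray, level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Fisher rejection indicator over all 2^n subsets.

    Returns (rejected, popcount) arrays of length 2^n; subset bit j set means
    feature j is in the intersection hypothesis.
    """
    n = terms.size
    size = 1 << n
    idx = np.arange(size, dtype=np.uint64)
    stat = np.zeros(size)
    popcnt = np.zeros(size, dtype=np.int64)
    for j in range(n):
        bit = ((idx >> np.uint64(j)) & np.uint64(1)).astype(bool)
        stat[bit] += terms[j]
        popcnt += bit
    with np.errstate(over="ignore"):
        thresh = stats.chi2.isf(level, 2 * np.arange(n + 1))
    thresh[0] = np.inf
    rejected = stat >= thresh[popcnt]
    # guard against ties at the boundary: Fisher rejects iff p <= level,
    # i.e. stat >= isf(level); equality included above
    return rejected, popcnt


def partial_bound_bruteforce(
    pvals,
    level: float,
    subset: Sequence[int] | None = None,
    local_test: str | Callable = "fisher",
    cap: int = BRUTE_FORCE_CAP,
    floor: float = 1e-300,
) -> int:
    """Closed-testing bound for ``subset`` by full enumeration of 2^{F_i}.

    ``pvals`` are the p-values of the focus set; ``subset`` gives positions
    within it (default: the full set).  The bound is
    ``|S| - max{|K ∩ S| : K ⊆ F_i not rejected at level}``, which equals the
    closed-testing bound because any non-rejected K certifies acceptance of
    all its subsets' intersection hypotheses.
    """
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if n > cap:
        raise ValueError(
            f"focus set of size {n} exceeds brute-force cap {cap}; "
            "use the Fisher fast path"
        )
    if subset is None:
        subset = range(n)
    sub = sorted(set(int(i) for i in subset))
    if any(i < 0 or i >= n for i in sub):
        raise IndexError("subset positions outside the focus set")
    if not sub:
        return 0
    smask = 0
    for i in sub:
        smask |= 1 << i
    if local_test == "fisher":
        terms = _neg2logs(p, floor)
        rejected, _ = _fisher_rejection_table(terms, level)
        idx = np.arange(1 << n, dtype=np.uint64)
        overlap = np.zeros(1 << n, dtype=np.int64)
        for i in sub:
            overlap += ((idx >> np.uint64(i)) & np.uint64(1)).astype(np.int64)
        best = int(overlap[~rejected].max())
    else:
        test = local_test
        if isinstance(test, str):
            from .local_tests import make_local_test

            test = make_local_test(test)
        best = 0
        for mask in range(1, 1 << n):
            members = [i for i in range(n) if mask >> i & 1]
            if not test(p[members], level):
                ov = bin(mask & smask).count("1")
                if ov > best:
                    best = ov
    return len(sub) - best


def fisher_subset_bound(pvals, subset: Sequence[int], level: float, floor: float = 1e-300) -> int:
    """Exact Fisher closed-testing bound d(S) for an arbitrary S, any size.

    For a candidate non-rejected set K with a = |K ∩ S| and b = |K \\ S|, the
    minimal Fisher statistic at fixed (a, b) takes the a largest p-values
    inside S and the b largest outside.  Scanning (a, b) gives
    max{|K ∩ S| : K not rejected} exactly, in O(|S|·|W\\S|) after sorting.
    """
    p = np.asarray(pvals, dtype=float)
    sub = np.zeros(p.size, dtype=bool)
    sub[np.asarray(list(subset), dtype=int)] = True
    if not sub.any():
        return 0
    terms_in = np.sort(_neg2logs(p[sub], floor))
    terms_out = np.sort(_neg2logs(p[~sub], floor))
    A = np.concatenate([[0.0], np.cumsum(terms_in)])  # a largest p's inside S
    B = np.concatenate([[0.0], np.cumsum(terms_out)])
    n_in, n_out = terms_in.size, terms_out.size
    with np.errstate(over="ignore"):
        thresh = stats.chi2.isf(level, 2 * np.arange(n_in + n_out + 1))
    thresh[0] = np.inf
    tot = A[:, None] + B[None, :]
    sizes = np.arange(n_in + 1)[:, None] + np.arange(n_out + 1)[None, :]
    feasible = (tot < thresh[sizes]) | (sizes == 0)
    best_a = int(np.nonzero(feasible.any(axis=1))[0].max())
    return n_in - best_a


class FisherPartialOracle:
    """Partial-bound oracle for one focus set under Fisher local tests.

    Full-set queries use the sorted-suffix fast path; strict subset queries
    use the exact size-stratified path (:func:`fisher_subset_bound`), so the
    oracle scales beyond enumerable focus sets.  Results are memoized per
    (rounded level, subset).
    """

    def __init__(
        self,
        focus_index: int,
        focus: frozenset[int],
        pvalues: Sequence[float] | np.ndarray,
        cap: int = BRUTE_FORCE_CAP,
        floor: float = 1e-300,
    ):
        self.focus_index = focus_index
        self.focus = frozenset(focus)
        self._order = sorted(self.focus)
        self._pos = {f: j for j, f in enumerate(self._order)}
        pv = np.asarray(pvalues, dtype=float)
        self._p = pv[self._order]  # pvalues indexed by universe feature index
        self.cap = cap
        self.floor = floor
        self._cache: dict[tuple[float, frozenset[int]], int] = {}

    def __call__(self, level: float, subset: frozenset[int]) -> int:
        subset = frozenset(subset)
        if not subset <= self.focus:
            raise ValueError("subset query outside the oracle's focus set")
        if not subset:
            return 0
        key = (_round_level(level), subset)
        if key not in self._cache:
            if subset == self.focus:
                val = fisher_fullset_bound(self._p, level, floor=self.floor)
            else:
                positions = [self._pos[f] for f in subset]
                val = fisher_subset_bound(self._p, positions, level, floor=self.floor)
            self._cache[key] = val
        return self._cache[key]


def fisher_partial_oracles(
    family: FocusFamily, pvalues: Sequence[float] | np.ndarray, **kw
) -> list[FisherPartialOracle]:
    """One Fisher partial-closed-testing oracle per focus set."""
    return [
        FisherPartialOracle(i, focus, pvalues, **kw)
        for i, focus in enumerate(family.members)
    ]


def bonferroni_partial_bounds(
    family: FocusFamily, oracles: Sequence[PartialBoundOracle], alpha: float
) -> tuple[int, ...]:
    """Per-focus-set full-set bounds d_i^{α/m}(F_i), no alpha recycling."""
    m = family.m
    return tuple(
        oracles[i](alpha / m, family.members[i]) for i in range(m)
    )


def holm_partial_bounds(
    family: FocusFamily,
    oracles: Sequence[PartialBoundOracle],
    alpha: float,
    max_rounds: int | None = None,
) -> HolmState:
    """Holm combination of partial procedures (sequential alpha recycling).

    Holm's factor h starts at m.  Each sweep recomputes d_i^{α/h}(F_i) for
    all focus sets not yet fully rejected; every set whose bound reaches
    |F_i| is then moved to the fully-rejected pool and h is set to the number
    of remaining sets.  Sweeps repeat until none is newly fully rejected.
    Early stopping via ``max_rounds`` retains error control (the bounds are
    then those of an intermediate, valid level).
    """
    m = family.m
    h = m
    bounds = [0] * m
    fully: set[int] = set()
    rounds = 0
    while True:
        rounds += 1
        for i in range(m):
            if i not in fully:
                bounds[i] = oracles[i](alpha / h, family.members[i])
        newly = {
            i
            for i in range(m)
            if i not in fully and bounds[i] == len(family.members[i])
        }
        if newly:
            fully |= newly
            h = max(1, m - len(fully))
        if (
            not newly
            or len(fully) == m
            or (max_rounds is not None and rounds >= max_rounds)
        ):
            break
    return HolmState(
        h=h,
        fully_rejected=frozenset(fully),
        bounds=tuple(bounds),
        alpha=alpha,
        rounds=rounds,
    )
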