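"""Combining partial bounds: trivial procedure, interpolation, greedy shortcut.

Starting from per-focus-set bounds d_i (Bonferroni at α/m or Holm at α/h),
the trivial procedure d⁰ assigns d_i to focus sets and 0 elsewhere.
Interpolation improves any bound function d via

    d'(S) = max_U  d(U) − |U \\ S| + d(S \\ U),

the rationale being that discoveries in U exceeding |U \\ S| must lie in S.
Iterating to a fixpoint yields the *coherent* procedure.  For large universes
the exact fixpoint is intractable; the greedy shortcut credits focus sets one
at a time in order of incremental contribution and is provably never above
the coherent bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .family import BoundTable, FocusFamily, HolmState, PartialBoundOracle
from .partial import bonferroni_partial_bounds, holm_partial_bounds

__all__ = [
    "trivial_bounds",
    "interpolate_once",
    "coherent_function",
    "coherent_bounds",
    "greedy_bound",
    "compute_bounds",
]

#: largest universe for which exact interpolation over 2^W is attempted
EXACT_CAP = 16
#: largest universe for the fully naive sweep (max over all U ∈ 2^W)
NAIVE_CAP = 12


def _mask(s: Iterable[int]) -> int:
    m = 0
    for i in s:
        m |= 1 << i
    return m


def _unmask(mask: int) -> frozenset[int]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return frozenset(out)


def _popcounts(size: int) -> np.ndarray:
    idx = np.arange(size, dtype=np.uint64)
    pc = np.zeros(size, dtype=np.int64)
    j = 0
    while (1 << j) < size:
        pc += ((idx >> np.uint64(j)) & np.uint64(1)).astype(np.int64)
        j += 1
    return pc


@dataclass
class BoundFunctionTable:
    """A bound function tabulated over every subset of a small universe."""

    w: int
    values: np.ndarray  # length 2^w, indexed by bitmask
    sweeps: int = 0

    def __call__(self, s: Iterable[int]) -> int:
        return int(self.values[_mask(s)])

    def as_dict(self) -> dict[frozenset[int], int]:
        return {_unmask(m): int(v) for m, v in enumerate(self.values)}


def trivial_bounds(
    family: FocusFamily, per_focus_bounds: Sequence[int]
) -> BoundFunctionTable:
    """The trivial procedure d⁰: d_i on focus sets, 0 elsewhere.

    If several focus sets coincide, the largest bound wins.  Exact
    (table-based) representation; requires |W| ≤ ``EXACT_CAP``.
    """
    w = family.universe.size
    if w > EXACT_CAP:
        raise ValueError(
            f"universe of size {w} exceeds exact cap {EXACT_CAP}; use greedy_bound"
        )
    values = np.zeros(1 << w, dtype=np.int64)
    for focus, d in zip(family.members, per_focus_bounds):
        m = _mask(focus)
        values[m] = max(values[m], int(d))
    return BoundFunctionTable(w=w, values=values, sweeps=0)


def _candidate_masks(family: FocusFamily) -> np.ndarray:
    """All unions of focus sets (including the empty union), as masks."""
    masks = {0}
    for focus in family.members:
        fm = _mask(focus)
        masks |= {m | fm for m in masks}
    return np.fromiter(masks, dtype=np.int64)


def _sweep(
    table: BoundFunctionTable, candidates: np.ndarray | None = None
) -> BoundFunctionTable:
    """One simultaneous interpolation round over every subset.

    ``candidates`` restricts the maximising U; None means all of 2^W.
    """
    w, old = table.w, table.values
    size = old.size
    pc = _popcounts(size)
    if candidates is None:
        cand = np.arange(size, dtype=np.int64)
    else:
        cand = candidates
    new = old.copy()
    all_s = np.arange(size, dtype=np.int64)
    for u in cand:
        u = int(u)
        # d(U) − |U \ S| + d(S \ U), vectorised over S
        contrib = old[u] - pc[u & ~all_s] + old[all_s & ~u]
        np.maximum(new, contrib, out=new)
    return BoundFunctionTable(w=w, values=new, sweeps=table.sweeps + 1)


def interpolate_once(
    table: BoundFunctionTable,
    s: Iterable[int] | None = None,
    family: FocusFamily | None = None,
):
    """One interpolation round.

    With ``s`` given, returns the improved integer bound d'(S) without
    touching the table; otherwise returns a new fully swept table.  When a
    ``family`` is passed, the maximisation is restricted to unions of focus
    sets (exact whenever the input is supported on focus sets, cheaper).
    """
    cand = _candidate_masks(family) if family is not None else None
    if s is None:
        return _sweep(table, cand)
    smask = _mask(s)
    old = table.values
    pc = _popcounts(old.size)
    if cand is None:
        cand = np.arange(old.size, dtype=np.int64)
    best = int(old[smask])
    for u in cand:
        u = int(u)
        best = max(best, int(old[u]) - int(pc[u & ~smask]) + int(old[smask & ~u]))
    return best


def coherent_function(
    family: FocusFamily,
    per_focus_bounds: Sequence[int],
    mode: str = "auto",
    max_sweeps: int = 64,
) -> BoundFunctionTable:
    """Iterate interpolation sweeps to the fixpoint (coherent procedure).

    ``mode``: 'naive' sweeps over all U ∈ 2^W (trust anchor, |W| ≤
    ``NAIVE_CAP``); 'restricted' sweeps over unions of focus sets (|W| ≤
    ``EXACT_CAP``); 'auto' picks naive when affordable.  The returned table's
    ``sweeps`` counts sweeps executed, including the final fixpoint-confirming
    one.
    """
    w = family.universe.size
    if mode == "auto":
        mode = "naive" if w <= NAIVE_CAP else "restricted"
    if mode == "naive":
        if w > NAIVE_CAP:
            raise ValueError(f"naive mode limited to |W| <= {NAIVE_CAP}")
        cand = None
    elif mode == "restricted":
        if w > EXACT_CAP:
            raise ValueError(
                f"universe of size {w} exceeds exact cap {EXACT_CAP}; use greedy_bound"
            )
        cand = _candidate_masks(family)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = trivial_bounds(family, per_focus_bounds)
    for _ in range(max_sweeps):
        new = _sweep(table, cand)
        if np.array_equal(new.values, table.values):
            table = new
            break
        table = new
    return table


def coherent_bounds(
    family: FocusFamily,
    per_focus_bounds: Sequence[int],
    queries: Sequence[Iterable[int]] | None = None,
    alpha: float | None = None,
    mode: str = "auto",
) -> BoundTable:
    """Coherent (fully interpolated) bounds for the queried sets.

    ``queries`` defaults to every subset of the universe.
    """
    table = coherent_function(family, per_focus_bounds, mode=mode)
    if queries is None:
        entries = table.as_dict()
    else:
        entries = {frozenset(q): table(q) for q in queries}
    return BoundTable(entries=entries, alpha=alpha, method_tag="coherent")


def greedy_bound(
    family: FocusFamily, per_focus_bounds: Sequence[int], s: Iterable[int]
) -> int:
    """Greedy shortcut d̂(S): credit focus sets by incremental contribution.

    Repeatedly pick the focus set maximising c_i = d_i − |F_i \\ S'| over the
    not-yet-credited part S' of S; credit c_i discoveries, strike F_i ∩ S'
    from S', retire the set.  Stops when no positive contribution remains.
    Ties break by larger |F_i ∩ S'|, then lower focus index.  The result
    never exceeds the coherent bound.
    """
    s_prime = set(s)
    remaining = set(range(family.m))
    total = 0
    while remaining and s_prime:
        best_key = None
        best_i = None
        for i in sorted(remaining):
            f = family.members[i]
            c = per_focus_bounds[i] - len(f - s_prime)
            if c > 0:
                key = (c, len(f & s_prime), -i)
                if best_key is None or key > best_key:
                    best_key = key
                    best_i = i
        if best_i is None:
            break
        total += best_key[0]
        s_prime -= family.members[best_i]
        remaining.discard(best_i)
    return total


def compute_bounds(
    family: FocusFamily,
    oracles: Sequence[PartialBoundOracle],
    alpha: float,
    queries: Sequence[Iterable[int]],
    method: str = "holm",
    mode: str = "greedy",
    max_rounds: int | None = None,
) -> tuple[BoundTable, HolmState | None]:
    """End-to-end: combine partial procedures and answer query sets.

    ``method`` selects Bonferroni (α/m) or Holm (α/h) per-focus bounds;
    ``mode`` selects the greedy shortcut (any size) or exact coherent bounds
    (small universes).  Returns the bound table plus the Holm state (None for
    Bonferroni).
    """
    state: HolmState | None = None
    if method == "holm":
        state = holm_partial_bounds(family, oracles, alpha, max_rounds=max_rounds)
        per_focus = state.bounds
    elif method == "bonferroni":
        per_focus = bonferroni_partial_bounds(family, oracles, alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    if mode == "greedy":
        entries = {
            frozenset(q): greedy_bound(family, per_focus, q) for q in queries
        }
        table = BoundTable(entries=entries, alpha=alpha, method_tag="greedy")
    elif mode == "exact":
        table = coherent_bounds(family, per_focus, queries=queries, alpha=alpha)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return table, state
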