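"""Feature universe, focus-set families, and partial-bound oracle contracts.

A *focus set* is a feature set fixed before seeing the data on which the user
wants concentrated power.  Every downstream procedure consumes a
:class:`FocusFamily` together with one :class:`PartialBoundOracle` per focus
set: a callable ``(level, subset) -> integer`` returning a lower confidence
bound on the number of true discoveries in ``subset`` of that focus set, valid
simultaneously over all subsets at the given level.

Features are referenced internally by dense integer indices ``0..w-1``;
external string identifiers are mapped at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

__all__ = [
    "FeatureUniverse",
    "FocusFamily",
    "PartialBoundOracle",
    "TableOracle",
    "BoundTable",
    "HolmState",
    "validate_family",
    "table_oracles",
]

#: number of decimal digits used when memoizing/matching significance levels
LEVEL_DIGITS = 12


def _round_level(level: float) -> float:
    return round(float(level), LEVEL_DIGITS)


class FeatureUniverse:
    """The whole feature set W, an ordered collection of w distinct ids."""

    def __init__(self, feature_ids: Iterable):
        ids = tuple(feature_ids)
        if len(ids) == 0:
            raise ValueError("feature universe must contain at least one feature")
        self._ids = ids
        self._index = {fid: i for i, fid in enumerate(ids)}
        if len(self._index) != len(ids):
            seen: set = set()
            for fid in ids:
                if fid in seen:
                    raise ValueError(f"duplicate feature id {fid!r} in universe")
                seen.add(fid)

    @property
    def feature_ids(self) -> tuple:
        return self._ids

    @property
    def size(self) -> int:
        return len(self._ids)

    def __len__(self) -> int:
        return len(self._ids)

    def index_of(self, feature_id) -> int:
        try:
            return self._index[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in universe") from None

    def indices_of(self, feature_ids: Iterable) -> frozenset[int]:
        return frozenset(self.index_of(f) for f in feature_ids)

    def ids_of(self, indices: Iterable[int]) -> tuple:
        return tuple(self._ids[i] for i in sorted(indices))

    def __contains__(self, feature_id) -> bool:
        return feature_id in self._index

    def __repr__(self) -> str:
        return f"FeatureUniverse(w={self.size})"


@dataclass(frozen=True)
class FocusFamily:
    """An ordered family F = {F_1, ..., F_m} of focus sets over a universe.

    ``members[i]`` holds the integer feature indices of F_{i+1}.  Sets may
    overlap; each must be nonempty and contained in the universe.
    """

    universe: FeatureUniverse
    members: tuple[frozenset[int], ...]
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"F{i + 1}" for i in range(len(self.members)))
            )
        if len(self.names) != len(self.members):
            raise ValueError("names and members length mismatch")

    @classmethod
    def from_id_sets(
        cls,
        universe: FeatureUniverse,
        sets: Sequence[Iterable] | Mapping[str, Iterable],
        names: Sequence[str] | None = None,
    ) -> "FocusFamily":
        """Build a family from collections of external feature ids."""
        if isinstance(sets, Mapping):
            names = tuple(sets.keys())
            sets = list(sets.values())
        members = []
        for s in sets:
            idx = frozenset(universe.index_of(f) for f in s)
            members.append(idx)
        fam = cls(universe, tuple(members), tuple(names) if names else ())
        return validate_family(fam)

    @property
    def m(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(f) for f in self.members)

    def overlap(self) -> dict[tuple[int, int], frozenset[int]]:
        """Pairwise nonempty intersections, keyed by (i, j) with i < j."""
        out = {}
        for i in range(self.m):
            for j in range(i + 1, self.m):
                inter = self.members[i] & self.members[j]
                if inter:
                    out[(i, j)] = inter
        return out

    def covering(self, subset: frozenset[int]) -> list[int]:
        """Indices i with F_i ∩ subset nonempty."""
        return [i for i, f in enumerate(self.members) if f & subset]


def validate_family(family: FocusFamily) -> FocusFamily:
    """Check family invariants; raise with the offending feature/set named."""
    w = family.universe.size
    if family.m < 1:
        raise ValueError("focus family must contain at least one set")
    for name, members in zip(family.names, family.members):
        if len(members) == 0:
            raise ValueError(f"focus set {name!r} is empty")
        for idx in members:
            if not (0 <= idx < w):
                raise ValueError(
                    f"focus set {name!r}: feature index {idx} not in universe"
                )
    return family


@runtime_checkable
class PartialBoundOracle(Protocol):
    """Contract for a partial true-discovery guarantee procedure on one F_i.

    ``oracle(level, subset)`` returns an integer in ``[0, |subset|]``, a lower
    confidence bound on true discoveries in ``subset ⊆ F_i`` valid
    simultaneously over all subsets of F_i at ``level``.  Implementations must
    be monotone nondecreasing in ``level`` and satisfy the interpolation floor
    ``oracle(level, S) <= oracle(level, T) + |S \\ T|`` for ``T ⊆ S``.
    """

    focus_index: int

    def __call__(self, level: float, subset: frozenset[int]) -> int: ...


class TableOracle:
    """Partial-bound oracle backed by tabulated full-set values.

    ``levels_to_bound`` maps significance level -> bound for the full focus
    set; a plain integer means the bound holds at every level.  Subset queries
    fall back on the interpolation floor ``max(0, d_i - |F_i \\ S|)`` unless a
    finer entry for ``(level, subset)`` was supplied.  A query at a level not
    tabulated is answered with the bound at the largest tabulated level below
    it (valid by level-monotonicity); if there is none, an error is raised.
    """

    def __init__(
        self,
        focus_index: int,
        focus: frozenset[int],
        levels_to_bound: int | Mapping[float, int],
        subset_entries: Mapping[tuple[float, frozenset[int]], int] | None = None,
    ):
        self.focus_index = focus_index
        self.focus = frozenset(focus)
        if isinstance(levels_to_bound, int):
            self._constant: int | None = levels_to_bound
            self._levels: list[tuple[float, int]] = []
        else:
            self._constant = None
            items = sorted(
                (_round_level(lv), int(b)) for lv, b in levels_to_bound.items()
            )
            for (l1, b1), (l2, b2) in zip(items, items[1:]):
                if b2 < b1:
                    raise ValueError(
                        f"table for focus set {focus_index}: bound not "
                        f"monotone in level ({b1}@{l1} > {b2}@{l2})"
                    )
            self._levels = items
        for lv, b in self._levels or (
            [(0.0, self._constant)] if self._constant is not None else []
        ):
            if not (0 <= b <= len(self.focus)):
                raise ValueError("tabulated bound outside [0, |F_i|]")
        self._subset_entries = {
            (_round_level(lv), frozenset(s)): int(b)
            for (lv, s), b in (subset_entries or {}).items()
        }

    def _full_bound(self, level: float) -> int:
        if self._constant is not None:
            return self._constant
        lv = _round_level(level)
        best = None
        for tab_level, bound in self._levels:
            if tab_level <= lv:
                best = bound
            else:
                break
        if best is None:
            raise ValueError(
                f"no tabulated bound at or below level {level} for focus set "
                f"{self.focus_index}"
            )
        return best

    def __call__(self, level: float, subset: frozenset[int]) -> int:
        subset = frozenset(subset)
        if not subset <= self.focus:
            raise ValueError("subset query outside the oracle's focus set")
        if not subset:
            return 0
        key = (_round_level(level), subset)
        if key in self._subset_entries:
            return self._subset_entries[key]
        d_full = self._full_bound(level)
        return max(0, min(len(subset), d_full - len(self.focus - subset)))


def table_oracles(
    family: FocusFamily,
    bounds: Mapping[int, int | Mapping[float, int]],
) -> list[TableOracle]:
    """One :class:`TableOracle` per focus set, keyed by 0-based focus index."""
    out = []
    for i, focus in enumerate(family.members):
        if i not in bounds:
            raise KeyError(f"no tabulated bounds for focus set index {i}")
        out.append(TableOracle(i, focus, bounds[i]))
    return out


@dataclass
class BoundTable:
    """Computed true-discovery lower bounds d(S) for queried sets."""

    entries: dict[frozenset[int], int]
    alpha: float | None = None
    method_tag: str = "bonferroni"

    def __post_init__(self):
        for s, b in self.entries.items():
            if not (0 <= b <= len(s)):
                raise ValueError(f"bound {b} outside [0, |S|] for |S|={len(s)}")

    def __getitem__(self, s: Iterable[int]) -> int:
        return self.entries[frozenset(s)]

    def tdp(self, s: Iterable[int]) -> float:
        s = frozenset(s)
        return self.entries[s] / len(s) if s else 0.0


@dataclass
class HolmState:
    """Converged state of the sequential alpha-recycling (Holm) combination.

    ``h`` is Holm's factor: the number of focus sets not yet fully rejected
    (floored at 1 when every set is fully rejected, so that α/h stays
    defined).  ``bounds[i]`` is d_i^{α/h}(F_i), frozen at |F_i| for fully
    rejected sets.
    """

    h: int
    fully_rejected: frozenset[int]
    bounds: tuple[int, ...]
    alpha: float
    rounds: int = 1

    def __post_init__(self):
        if self.h < 1:
            raise ValueError("Holm factor must be >= 1")
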