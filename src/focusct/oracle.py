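"""Explicit closed testing over the full universe, for verification.

Closed testing rejects an intersection hypothesis H_S only when every
intersection hypothesis containing it is rejected by a local test.  Three
local tests are built from the partial procedures:

* ``phi``      — rejects H_S when some partial procedure finds a discovery in
                 F_i ∩ S at level α/m_S (m_S = number of focus sets meeting S);
* ``phi_tilde``— the first shortcut, using only full-set bounds:
                 d_i^{α/m_S}(F_i) > |F_i \\ S| for some i;
* ``phi_bar``  — the second shortcut, using the converged Holm bounds
                 d_i^{α/h}(F_i) > |F_i \\ S|.

``phi_bar`` is monotone in S, so its closure ψ̄ equals φ̄ itself and its
closed-testing bound coincides with the coherent interpolated procedure.
This module exists to verify those relations and to measure the power gaps
between the shortcuts; it enumerates the subset lattice and is meant for
small universes only.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .family import FocusFamily, HolmState, PartialBoundOracle, TableOracle
from .partial import FisherPartialOracle, _fisher_rejection_table, _neg2logs

__all__ = ["m_s", "ClosedTestingOracle", "ENUM_CAP"]

#: largest universe enumerated by the oracle
ENUM_CAP = 16

VARIANTS = ("phi", "phi_tilde", "phi_bar")


def m_s(family: FocusFamily, s: Iterable[int]) -> int:
    """Number of focus sets with nonempty intersection with S."""
    s = frozenset(s)
    return sum(1 for f in family.members if f & s)


def _superset_or(flags: np.ndarray, w: int) -> np.ndarray:
    """flags'[J] = OR over K ⊇ J of flags[K] (subset-lattice zeta transform)."""
    out = flags.copy()
    idx = np.arange(out.size)
    for j in range(w):
        lo = (idx >> j) & 1 == 0
        out[lo] |= out[idx[lo] | (1 << j)]
    return out


def _subset_max(values: np.ndarray, w: int) -> np.ndarray:
    """out[S] = max over J ⊆ S of values[J]."""
    out = values.copy()
    idx = np.arange(out.size)
    for j in range(w):
        hi = (idx >> j) & 1 == 1
        out[hi] = np.maximum(out[hi], out[idx[hi] ^ (1 << j)])
    return out


class ClosedTestingOracle:
    """Closed testing with one of the three local-test variants.

    Tabulates φ, ψ and the closed-testing bound d over the whole subset
    lattice (lazily, on first query).  ``phi_bar`` requires a converged
    :class:`~focusct.family.HolmState`; the other variants require per-focus
    oracles answering at levels α/k, k = 1..m (``phi`` additionally needs
    subset queries).
    """

    def __init__(
        self,
        family: FocusFamily,
        alpha: float,
        variant: str = "phi_bar",
        oracles: Sequence[PartialBoundOracle] | None = None,
        holm_state: HolmState | None = None,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if variant == "phi_bar" and holm_state is None:
            raise ValueError("phi_bar requires a converged HolmState")
        if variant != "phi_bar" and oracles is None:
            raise ValueError(f"{variant} requires per-focus oracles")
        w = family.universe.size
        if w > ENUM_CAP:
            raise ValueError(
                f"universe of size {w} exceeds enumeration cap {ENUM_CAP}"
            )
        self.family = family
        self.alpha = float(alpha)
        self.variant = variant
        self.oracles = list(oracles) if oracles is not None else None
        self.holm_state = holm_state
        self._tables: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- lattice tabulation -------------------------------------------------

    def _base_arrays(self):
        w = self.family.universe.size
        size = 1 << w
        idx = np.arange(size, dtype=np.int64)
        overlaps = []
        for focus in self.family.members:
            ov = np.zeros(size, dtype=np.int64)
            for b in focus:
                ov += (idx >> b) & 1
            overlaps.append(ov)
        m_s_arr = np.sum([ov > 0 for ov in overlaps], axis=0).astype(np.int64)
        return w, size, idx, overlaps, m_s_arr

    def _phi_table(self) -> np.ndarray:
        w, size, idx, overlaps, m_s_arr = self._base_arrays()
        fam = self.family
        m = fam.m
        phi = np.zeros(size, dtype=bool)
        if self.variant == "phi_bar":
            bounds = self.holm_state.bounds
            for i, focus in enumerate(fam.members):
                fi = len(focus)
                phi |= bounds[i] > (fi - overlaps[i])
            return phi
        # full-set bounds at every candidate level alpha/k
        d_full = np.zeros((m, m + 1), dtype=np.int64)
        for i, focus in enumerate(fam.members):
            for k in range(1, m + 1):
                d_full[i, k] = self.oracles[i](self.alpha / k, focus)
        if self.variant == "phi_tilde":
            for i, focus in enumerate(fam.members):
                fi = len(focus)
                with np.errstate(invalid="ignore"):
                    cond = d_full[i, np.maximum(m_s_arr, 1)] > (fi - overlaps[i])
                phi |= cond & (overlaps[i] > 0)
            return phi
        # variant phi: needs d_i^{alpha/m_S}(F_i ∩ S) > 0
        for i, focus in enumerate(fam.members):
            phi |= self._phi_subset_condition(i, idx, overlaps[i], m_s_arr)
        return phi

    def _phi_subset_condition(self, i, idx, overlap_i, m_s_arr) -> np.ndarray:
        """Indicator over all S of d_i^{α/m_S}(F_i ∩ S) > 0."""
        fam = self.family
        m = fam.m
        focus = sorted(fam.members[i])
        fi = len(focus)
        oracle = self.oracles[i]
        # position of each S inside 2^{F_i}
        sub_idx = np.zeros(idx.size, dtype=np.int64)
        for j, b in enumerate(focus):
            sub_idx += ((idx >> b) & 1) << j
        cond = np.zeros(idx.size, dtype=bool)
        if isinstance(oracle, FisherPartialOracle):
            # d_i(S') > 0 iff no non-rejected K ⊆ F_i contains S'
            for k in range(1, m + 1):
                rejected, _ = _fisher_rejection_table(
                    _neg2logs(oracle._p, oracle.floor), self.alpha / k
                )
                accepted_superset = _superset_or(~rejected, fi)
                sel = m_s_arr == k
                cond[sel] = ~accepted_superset[sub_idx[sel]] & (sub_idx[sel] > 0)
            return cond
        if isinstance(oracle, TableOracle) and not oracle._subset_entries:
            # interpolation-floor oracle: d_i(S') > 0 iff d_i(F_i) > |F_i \ S|
            for k in range(1, m + 1):
                d = oracle(self.alpha / k, oracle.focus)
                sel = m_s_arr == k
                cond[sel] = (d > (fi - overlap_i[sel])) & (overlap_i[sel] > 0)
            return cond
        # generic oracle: direct subset queries
        members = np.array(focus)
        for s_mask in range(idx.size):
            if overlap_i[s_mask] == 0:
                continue
            sub = frozenset(
                int(b) for b in members if (s_mask >> int(b)) & 1
            )
            cond[s_mask] = oracle(self.alpha / int(m_s_arr[s_mask]), sub) > 0
        return cond

    def _build(self):
        if self._tables is not None:
            return self._tables
        w = self.family.universe.size
        size = 1 << w
        pc = np.zeros(size, dtype=np.int64)
        idx = np.arange(size, dtype=np.int64)
        for j in range(w):
            pc += (idx >> j) & 1
        phi = self._phi_table()
        if self.variant == "phi_bar":
            # φ̄ is monotone in S, hence ψ̄ = φ̄
            psi = phi.copy()
        else:
            accepted_superset = _superset_or(~phi, w)
            psi = ~accepted_superset
        best = np.where(~psi, pc, np.int64(-(10**9)))
        best = _subset_max(best, w)
        bound = pc - best
        self._tables = (phi.astype(np.int8), psi.astype(np.int8), bound)
        return self._tables

    # -- public queries -----------------------------------------------------

    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(φ, ψ, d) over all 2^w subsets, indexed by bitmask."""
        return self._build()

    def _mask(self, s: Iterable[int]) -> int:
        m = 0
        for i in s:
            m |= 1 << int(i)
        return m

    def local_test(self, s: Iterable[int]) -> int:
        """φ(S): 1 iff the variant's local test rejects H_S (0 if m_S = 0)."""
        phi, _, _ = self._build()
        return int(phi[self._mask(s)])

    def psi(self, s: Iterable[int]) -> int:
        """ψ(S) = min{φ(K) : S ⊆ K ⊆ W}."""
        _, psi, _ = self._build()
        return int(psi[self._mask(s)])

    def ct_bound(self, s: Iterable[int]) -> int:
        """Closed-testing true-discovery bound d(S) = min{|S\\J| : ψ(J)=0}."""
        _, _, bound = self._build()
        return int(bound[self._mask(s)])
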