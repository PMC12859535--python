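"""Randomised verification of the shortcut relations on enumerable instances.

Each instance draws a small universe, a random focus family and valid
partial-bound oracles (tabulated or Fisher partial closed testing), then
checks the ordering and equality relations that tie the combination
procedure to full closed testing:

* Holm bounds dominate Bonferroni bounds componentwise;
* greedy shortcut ≤ coherent interpolated bound for every query set;
* φ̄ ≤ φ̃ ≤ φ pointwise, with φ̃ = φ on sets that split every focus set
  cleanly (F_i ∩ S ∈ {F_i, ∅} for all i);
* ψ̄ = φ̄ (the Holm local test is its own closure);
* the coherent interpolation fixpoint never exceeds the φ̄ closed-testing
  bound, with exact equality on pairwise disjoint focus families (for
  overlapping families closed testing can be strictly sharper: joint
  counting over several overlapping constraints is lost by pairwise
  interpolation — see the documented counterexample in the tests);
* closed-testing bounds order as d ≥ d̃ ≥ d̄;
* ψ is monotone on the subset lattice for every variant.

This is the package's trust anchor; the CLI exposes it as ``focusct verify``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .combine import coherent_function, greedy_bound
from .family import FocusFamily, FeatureUniverse, TableOracle
from .oracle import ClosedTestingOracle, _superset_or
from .partial import (
    FisherPartialOracle,
    bonferroni_partial_bounds,
    holm_partial_bounds,
)

__all__ = ["LemmaSuiteResult", "run_lemma_suite", "random_instance"]

CHECKS = (
    "holm_ge_bonferroni",
    "greedy_le_coherent",
    "greedy_ge_focus_bound",
    "phi_ordering",
    "phi_equality_on_aligned_sets",
    "psi_bar_equals_phi_bar",
    "coherent_le_dbar",
    "dbar_equals_coherent_disjoint",
    "bound_ordering",
    "psi_monotone",
    "restricted_equals_naive",
)


@dataclass
class LemmaSuiteResult:
    instances: int = 0
    checks: int = 0
    violations: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CHECKS})

    @property
    def ok(self) -> bool:
        return all(v == 0 for v in self.violations.values())

    def summary(self) -> str:
        lines = [f"instances: {self.instances}, checks: {self.checks}"]
        for name, count in self.violations.items():
            lines.append(f"  {name}: {'ok' if count == 0 else f'{count} VIOLATIONS'}")
        return "\n".join(lines)


def _random_family(
    rng: np.random.Generator, w: int, m: int, disjoint: bool = False
) -> FocusFamily:
    universe = FeatureUniverse(range(w))
    if disjoint:
        perm = rng.permutation(w)
        if m > 1:
            cuts = sorted(
                rng.choice(range(1, w), size=min(m - 1, w - 1), replace=False)
            )
            parts = np.split(perm, cuts)
        else:
            parts = [perm]
        members = tuple(
            frozenset(int(x) for x in part) for part in parts if len(part)
        )
    else:
        members = tuple(
            frozenset(
                rng.choice(
                    w, size=int(rng.integers(1, min(w, 6) + 1)), replace=False
                ).tolist()
            )
            for _ in range(m)
        )
    return FocusFamily(universe, members)


def _random_table_oracles(rng, family: FocusFamily, alpha: float):
    """Valid tabulated oracles: bounds nondecreasing in the level."""
    m = family.m
    oracles = []
    for i, focus in enumerate(family.members):
        fi = len(focus)
        levels = sorted(alpha / k for k in range(1, m + 1))
        vals = np.sort(rng.integers(0, fi + 1, size=len(levels)))
        oracles.append(TableOracle(i, focus, dict(zip(levels, vals.tolist()))))
    return oracles


def _random_fisher_oracles(rng, family: FocusFamily):
    w = family.universe.size
    p = rng.uniform(size=w)
    signal = rng.uniform(size=w) < 0.5
    p[signal] = 10.0 ** (-rng.uniform(0.5, 8.0, size=int(signal.sum())))
    return [
        FisherPartialOracle(i, focus, p) for i, focus in enumerate(family.members)
    ]


def random_instance(
    rng: np.random.Generator, kind: str = "table", disjoint: bool = False
):
    """(family, oracles, alpha) for one randomised verification instance."""
    if kind == "table":
        w = int(rng.integers(4, 11))
        m = int(rng.integers(1, 5))
        family = _random_family(rng, w, m, disjoint=disjoint)
        alpha = float(rng.choice([0.05, 0.1, 0.2]))
        oracles = _random_table_oracles(rng, family, alpha)
    elif kind == "fisher":
        w = int(rng.integers(4, 10))
        m = int(rng.integers(1, 4))
        family = _random_family(rng, w, m, disjoint=disjoint)
        alpha = float(rng.choice([0.05, 0.1]))
        oracles = _random_fisher_oracles(rng, family)
    else:
        raise ValueError(f"unknown instance kind {kind!r}")
    return family, oracles, alpha


def _aligned_masks(family: FocusFamily) -> np.ndarray:
    """Masks S with F_i ∩ S ∈ {∅, F_i} for every i (the equality condition
    of the first-shortcut lemma; for overlapping families this is stricter
    than being a union of focus sets)."""
    w = family.universe.size
    idx = np.arange(1 << w, dtype=np.int64)
    ok = np.ones(idx.size, dtype=bool)
    for focus in family.members:
        ov = np.zeros(idx.size, dtype=np.int64)
        for b in focus:
            ov += (idx >> b) & 1
        ok &= (ov == 0) | (ov == len(focus))
    return idx[ok]


def _psi_monotone_ok(psi: np.ndarray, w: int) -> bool:
    idx = np.arange(psi.size)
    for j in range(w):
        lo = (idx >> j) & 1 == 0
        if np.any(psi[lo] > psi[idx[lo] | (1 << j)]):
            return False
    return True


def check_instance(
    family: FocusFamily,
    oracles,
    alpha: float,
    rng: np.random.Generator,
    result: LemmaSuiteResult,
    greedy_sample: int = 128,
) -> None:
    """Run every lemma check on one instance, tallying violations."""
    w = family.universe.size
    size = 1 << w

    bonf = np.array(bonferroni_partial_bounds(family, oracles, alpha))
    state = holm_partial_bounds(family, oracles, alpha)
    holm = np.array(state.bounds)
    result.checks += 1
    if np.any(holm < bonf):
        result.violations["holm_ge_bonferroni"] += 1

    mode = "naive" if w <= 8 else "restricted"
    coherent = coherent_function(family, holm, mode=mode)
    if w <= 8:
        restricted = coherent_function(family, holm, mode="restricted")
        result.checks += 1
        if not np.array_equal(coherent.values, restricted.values):
            result.violations["restricted_equals_naive"] += 1

    # greedy never exceeds the coherent bound; picking F_i first is available
    if w <= 8:
        query_masks = range(size)
    else:
        query_masks = rng.integers(0, size, size=greedy_sample).tolist()
    result.checks += 1
    for mask in query_masks:
        s = frozenset(i for i in range(w) if (int(mask) >> i) & 1)
        if greedy_bound(family, holm, s) > int(coherent.values[int(mask)]):
            result.violations["greedy_le_coherent"] += 1
            break
    result.checks += 1
    for i, focus in enumerate(family.members):
        if greedy_bound(family, holm, focus) < holm[i]:
            result.violations["greedy_ge_focus_bound"] += 1
            break

    ct = {
        v: ClosedTestingOracle(
            family,
            alpha,
            variant=v,
            oracles=oracles,
            holm_state=state if v == "phi_bar" else None,
        )
        for v in ("phi", "phi_tilde", "phi_bar")
    }
    phi, psi, bound = {}, {}, {}
    for v, oracle in ct.items():
        phi[v], psi[v], bound[v] = oracle.tables()

    result.checks += 1
    if np.any(phi["phi_bar"] > phi["phi_tilde"]) or np.any(
        phi["phi_tilde"] > phi["phi"]
    ):
        result.violations["phi_ordering"] += 1
    result.checks += 1
    am = _aligned_masks(family)
    if np.any(phi["phi_tilde"][am] != phi["phi"][am]):
        result.violations["phi_equality_on_aligned_sets"] += 1

    # ψ̄ recomputed by the generic superset transform must equal φ̄ itself
    result.checks += 1
    psi_bar_generic = ~_superset_or(phi["phi_bar"] == 0, w)
    if np.any(psi_bar_generic.astype(np.int8) != phi["phi_bar"]):
        result.violations["psi_bar_equals_phi_bar"] += 1

    # interpolation can only lose against closed testing with the same
    # per-focus bounds; for disjoint families it loses nothing
    result.checks += 1
    if np.any(coherent.values > bound["phi_bar"]):
        result.violations["coherent_le_dbar"] += 1
    pairwise_disjoint = all(
        not (family.members[i] & family.members[j])
        for i in range(family.m)
        for j in range(i + 1, family.m)
    )
    if pairwise_disjoint:
        result.checks += 1
        if not np.array_equal(bound["phi_bar"], coherent.values):
            result.violations["dbar_equals_coherent_disjoint"] += 1

    result.checks += 1
    if np.any(bound["phi"] < bound["phi_tilde"]) or np.any(
        bound["phi_tilde"] < bound["phi_bar"]
    ):
        result.violations["bound_ordering"] += 1

    result.checks += 1
    if not all(_psi_monotone_ok(psi[v], w) for v in psi):
        result.violations["psi_monotone"] += 1


def run_lemma_suite(
    seed: int = 0,
    n_instances: int = 2000,
    fisher_fraction: float = 0.25,
    disjoint_fraction: float = 0.25,
) -> LemmaSuiteResult:
    """Run the full randomised lemma suite; all violation counts should be 0.

    A ``disjoint_fraction`` of the instances use pairwise disjoint focus
    families, on which the coherent fixpoint must *equal* the explicit
    closed-testing bound; on overlapping families only the conservative
    inequality is claimed (see the counterexample in the test suite).
    """
    rng = np.random.default_rng(seed)
    result = LemmaSuiteResult()
    n_fisher = int(round(fisher_fraction * n_instances))
    kinds = ["fisher"] * n_fisher + ["table"] * (n_instances - n_fisher)
    n_disjoint = int(round(disjoint_fraction * n_instances))
    flags = [True] * n_disjoint + [False] * (n_instances - n_disjoint)
    rng.shuffle(flags)
    for kind, disjoint in zip(kinds, flags):
        family, oracles, alpha = random_instance(rng, kind, disjoint=disjoint)
        check_instance(family, oracles, alpha, rng, result)
        result.instances += 1
    return result
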