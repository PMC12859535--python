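import numpy as np
import pytest

from focusct import FeatureUniverse, FocusFamily, TableOracle, table_oracles
from focusct.combine import coherent_function
from focusct.oracle import ClosedTestingOracle, _superset_or, m_s
from focusct.partial import fisher_partial_oracles, holm_partial_bounds
from focusct.synthetic import gen_focus_structure, gen_two_group
from focusct.local_tests import two_sample_t_pvalues


def _idx(universe, ids):
    return universe.indices_of(ids)


class TestMS:
    def test_shared_feature_counts_both_sets(self, toy_universe, toy_family):
        assert m_s(toy_family, _idx(toy_universe, [2])) == 2

    def test_uncovered_feature(self, toy_universe, toy_family):
        assert m_s(toy_family, _idx(toy_universe, [3])) == 0

    def test_whole_universe(self, toy_universe, toy_family):
        assert m_s(toy_family, _idx(toy_universe, [1, 2, 3, 4])) == toy_family.m


class TestLocalTests:
    def test_phi_tilde_on_toy_nonfocus_set(
        self, toy_universe, toy_family, toy_oracles
    ):
        # d2 = 2 > |F2 \ {2,3}| = 1, so the local test rejects
        ct = ClosedTestingOracle(
            toy_family, 0.05, variant="phi_tilde", oracles=toy_oracles
        )
        assert ct.local_test(_idx(toy_universe, [2, 3])) == 1

    def test_uncovered_sets_never_rejected(self, toy_universe, toy_family, toy_oracles):
        state = holm_partial_bounds(toy_family, toy_oracles, 0.05)
        for variant, kw in [
            ("phi", {"oracles": toy_oracles}),
            ("phi_tilde", {"oracles": toy_oracles}),
            ("phi_bar", {"holm_state": state}),
        ]:
            ct = ClosedTestingOracle(toy_family, 0.05, variant=variant, **kw)
            assert ct.local_test(_idx(toy_universe, [3])) == 0
            assert ct.local_test(frozenset()) == 0

    def test_variant_validation(self, toy_family, toy_oracles):
        with pytest.raises(ValueError, match="variant"):
            ClosedTestingOracle(toy_family, 0.05, variant="x", oracles=toy_oracles)
        with pytest.raises(ValueError, match="HolmState"):
            ClosedTestingOracle(toy_family, 0.05, variant="phi_bar")
        with pytest.raises(ValueError, match="oracles"):
            ClosedTestingOracle(toy_family, 0.05, variant="phi")


class TestCTBound:
    def test_phi_bar_reproduces_toy_coherent_column(
        self, toy_universe, toy_family, toy_oracles, toy_table
    ):
        state = holm_partial_bounds(toy_family, toy_oracles, 0.05)
        ct = ClosedTestingOracle(toy_family, 0.05, variant="phi_bar", holm_state=state)
        for ids, (_, _, e2) in toy_table.items():
            assert ct.ct_bound(_idx(toy_universe, ids)) == e2

    def test_global_null_oracles_give_zero_everywhere(self, toy_family):
        oracles = table_oracles(toy_family, {0: 0, 1: 0})
        state = holm_partial_bounds(toy_family, oracles, 0.05)
        for variant, kw in [
            ("phi", {"oracles": oracles}),
            ("phi_tilde", {"oracles": oracles}),
            ("phi_bar", {"holm_state": state}),
        ]:
            ct = ClosedTestingOracle(toy_family, 0.05, variant=variant, **kw)
            _, _, bound = ct.tables()
            assert np.all(bound == 0)

    def test_enumeration_cap(self):
        universe = FeatureUniverse(range(20))
        fam = FocusFamily(universe, (frozenset({0}),))
        with pytest.raises(ValueError, match="cap"):
            ClosedTestingOracle(
                fam, 0.05, variant="phi", oracles=[TableOracle(0, frozenset({0}), 1)]
            )

    def test_psi_monotone_on_toy(self, toy_family, toy_oracles):
        ct = ClosedTestingOracle(toy_family, 0.05, variant="phi", oracles=toy_oracles)
        _, psi, _ = ct.tables()
        idx = np.arange(psi.size)
        for j in range(4):
            lo = (idx >> j) & 1 == 0
            assert np.all(psi[lo] <= psi[idx[lo] | (1 << j)])


class TestTypeIError:
    def test_phi_rejection_rate_under_global_null(self, rng):
        """Under a fully null configuration, P(φ(S)=1) stays near α for the
        all-feature set (Fisher partial closed testing local bounds)."""
        reps, alpha, w = 2000, 0.05, 6
        universe = FeatureUniverse(range(w))
        fam = FocusFamily(
            universe, (frozenset({0, 1, 2}), frozenset({2, 3, 4, 5}))
        )
        full = frozenset(range(w))
        hits = 0
        for _ in range(reps):
            p = rng.uniform(size=w)
            oracles = fisher_partial_oracles(fam, p)
            # φ(W) rejects iff some partial procedure finds a discovery in
            # its focus set at level α/m_W
            hits += any(
                oracles[i](alpha / fam.m, f) > 0
                for i, f in enumerate(fam.members)
            )
        rate = hits / reps
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)


class TestSimultaneousCoverageReduction:
    def test_violation_anywhere_iff_local_test_rejects_null_set(self, rng):
        """The event 'some bound d̄(S) exceeds |S ∩ W₁|' is exactly
        'φ̄(W₀) = 1'; verified exhaustively on small random instances."""
        for _ in range(40):
            w = int(rng.integers(4, 9))
            n = 30
            X, y, truth = gen_two_group(
                n=n, w=w, signal_prop=0.5, mu=1.0, seed=rng
            )
            universe = FeatureUniverse(range(w))
            members = tuple(
                frozenset(rng.choice(w, size=3, replace=False)) for _ in range(2)
            )
            fam = FocusFamily(universe, members)
            pvals = two_sample_t_pvalues(X, y)
            oracles = fisher_partial_oracles(fam, pvals)
            state = holm_partial_bounds(fam, oracles, 0.05)
            ct = ClosedTestingOracle(fam, 0.05, variant="phi_bar", holm_state=state)
            _, _, bound = ct.tables()
            w1 = truth.w1
            idx = np.arange(1 << w)
            true_count = np.zeros(1 << w, dtype=int)
            for b in w1:
                true_count += (idx >> b) & 1
            any_violation = bool(np.any(bound > true_count))
            local_reject = any(
                d > len(f & w1) for d, f in zip(state.bounds, fam.members)
            )
            assert any_violation == local_reject


class TestShortcutOrdering:
    def test_bound_and_test_ordering_with_fisher_oracles(self, rng):
        for _ in range(25):
            w = int(rng.integers(4, 9))
            m = int(rng.integers(1, 4))
            universe = FeatureUniverse(range(w))
            members = tuple(
                frozenset(
                    rng.choice(w, size=int(rng.integers(1, 5)), replace=False)
                )
                for _ in range(m)
            )
            fam = FocusFamily(universe, members)
            p = rng.uniform(size=w) ** rng.uniform(0.5, 8)
            oracles = fisher_partial_oracles(fam, p)
            state = holm_partial_bounds(fam, oracles, 0.05)
            phi, _, b_phi = ClosedTestingOracle(
                fam, 0.05, variant="phi", oracles=oracles
            ).tables()
            phit, _, b_tilde = ClosedTestingOracle(
                fam, 0.05, variant="phi_tilde", oracles=oracles
            ).tables()
            phib, psib, b_bar = ClosedTestingOracle(
                fam, 0.05, variant="phi_bar", holm_state=state
            ).tables()
            assert np.all(phib <= phit) and np.all(phit <= phi)
            assert np.all(b_phi >= b_tilde) and np.all(b_tilde >= b_bar)
            # ψ̄ recomputed generically equals φ̄ (monotone local test)
            psi_generic = ~_superset_or(phib == 0, w)
            assert np.array_equal(psi_generic.astype(np.int8), phib)
            # interpolation is a conservative shortcut to the φ̄ closure
            coherent = coherent_function(fam, state.bounds)
            assert np.all(coherent.values <= b_bar)

    def test_coherent_equals_ct_bound_on_disjoint_families(self, rng):
        for _ in range(25):
            w = int(rng.integers(4, 10))
            m = int(rng.integers(1, 4))
            universe = FeatureUniverse(range(w))
            perm = rng.permutation(w)
            cuts = (
                sorted(rng.choice(range(1, w), size=m - 1, replace=False))
                if m > 1
                else []
            )
            members = tuple(
                frozenset(int(x) for x in part)
                for part in np.split(perm, cuts)
                if len(part)
            )
            fam = FocusFamily(universe, members)
            p = rng.uniform(size=w) ** rng.uniform(0.5, 8)
            oracles = fisher_partial_oracles(fam, p)
            state = holm_partial_bounds(fam, oracles, 0.05)
            _, _, b_bar = ClosedTestingOracle(
                fam, 0.05, variant="phi_bar", holm_state=state
            ).tables()
            coherent = coherent_function(fam, state.bounds)
            assert np.array_equal(b_bar, coherent.values)

    def test_overlapping_family_counterexample_to_exact_equality(self):
        """With three mutually overlapping focus sets, the explicit closed
        testing bound can be strictly sharper than the interpolation
        fixpoint: interpolation subtracts overlap elements once per chain
        step, while closed testing counts them jointly.  This bounds what
        the interpolation/greedy shortcuts can promise: they are
        conservative, not exact, under overlap."""
        universe = FeatureUniverse(range(9))
        fam = FocusFamily(
            universe,
            (
                frozenset({1, 2, 3, 4, 7}),
                frozenset({1, 4, 6}),
                frozenset({2, 5, 6, 7}),
            ),
        )
        bounds = (3, 2, 1)
        oracles = table_oracles(fam, dict(enumerate(bounds)))
        state = holm_partial_bounds(fam, oracles, 0.05)
        assert state.bounds == bounds
        ct = ClosedTestingOracle(fam, 0.05, variant="phi_bar", holm_state=state)
        coherent = coherent_function(fam, bounds, mode="naive")
        s = frozenset({1, 2, 5, 6, 7})
        assert coherent(s) == 1
        assert ct.ct_bound(s) == 2  # strictly sharper
        _, _, b_bar = ct.tables()
        assert np.all(coherent.values <= b_bar)
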