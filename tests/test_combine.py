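import numpy as np
import pytest

from focusct import FeatureUniverse, FocusFamily
from focusct.combine import (
    coherent_bounds,
    coherent_function,
    compute_bounds,
    greedy_bound,
    interpolate_once,
    trivial_bounds,
)
from focusct.verify import random_instance
from focusct.partial import holm_partial_bounds


def _idx(universe, ids):
    return universe.indices_of(ids)


class TestTrivial:
    def test_focus_sets_get_their_bound(self, toy_universe, toy_family, toy_bounds):
        d0 = trivial_bounds(toy_family, toy_bounds)
        assert d0(_idx(toy_universe, [2, 4])) == 2
        assert d0(_idx(toy_universe, [1, 2])) == 1

    def test_nonfocus_sets_get_zero(self, toy_universe, toy_family, toy_bounds):
        d0 = trivial_bounds(toy_family, toy_bounds)
        assert d0(_idx(toy_universe, [2, 3])) == 0
        assert d0(frozenset()) == 0

    def test_coinciding_focus_sets_take_maximum(self, toy_universe):
        fam = FocusFamily.from_id_sets(toy_universe, [[1, 2], [1, 2]])
        d0 = trivial_bounds(fam, (1, 2))
        assert d0(_idx(toy_universe, [1, 2])) == 2

    def test_exact_cap(self):
        universe = FeatureUniverse(range(20))
        fam = FocusFamily(universe, (frozenset({0}),))
        with pytest.raises(ValueError, match="greedy"):
            trivial_bounds(fam, (1,))


class TestInterpolation:
    def test_worked_nonfocus_value(self, toy_universe, toy_family, toy_bounds):
        # d(1)({2,3}) = d(0)({2,4}) - |{4}| + d(0)({3}) = 2 - 1 + 0 = 1
        d0 = trivial_bounds(toy_family, toy_bounds)
        assert interpolate_once(d0, _idx(toy_universe, [2, 3])) == 1

    def test_value_not_improvable_in_one_round(
        self, toy_universe, toy_family, toy_bounds
    ):
        d0 = trivial_bounds(toy_family, toy_bounds)
        assert interpolate_once(d0, _idx(toy_universe, [1, 3])) == 0

    def test_superset_of_fully_rejected_focus_set(self, toy_universe):
        fam = FocusFamily.from_id_sets(toy_universe, [[1, 2]])
        d0 = trivial_bounds(fam, (2,))
        assert interpolate_once(d0, _idx(toy_universe, [1, 2, 3])) >= 2

    def test_sweep_never_decreases(self, rng):
        for _ in range(30):
            family, _, _ = random_instance(rng, "table")
            bounds = [
                int(rng.integers(0, len(f) + 1)) for f in family.members
            ]
            table = trivial_bounds(family, bounds)
            for _ in range(3):
                new = interpolate_once(table)
                assert np.all(new.values >= table.values)
                table = new

    def test_restricted_candidates_match_full_sweep(self, rng):
        for _ in range(30):
            family, _, _ = random_instance(rng, "table")
            if family.universe.size > 8:
                continue
            bounds = [int(rng.integers(0, len(f) + 1)) for f in family.members]
            full = coherent_function(family, bounds, mode="naive")
            restricted = coherent_function(family, bounds, mode="restricted")
            assert np.array_equal(full.values, restricted.values)


class TestCoherent:
    def test_toy_reproduces_published_columns(
        self, toy_universe, toy_family, toy_bounds, toy_table
    ):
        d0 = trivial_bounds(toy_family, toy_bounds)
        d1 = interpolate_once(d0)
        d2 = interpolate_once(d1)
        for ids, (e0, e1, e2) in toy_table.items():
            s = _idx(toy_universe, ids)
            assert d0(s) == e0
            assert d1(s) == e1
            assert d2(s) == e2

    def test_toy_converges_after_two_sweeps(
        self, toy_family, toy_bounds
    ):
        table = coherent_function(toy_family, toy_bounds, mode="naive")
        # one improving sweep plus the confirming fixpoint sweep
        assert table.sweeps == 2

    def test_single_focus_set_equal_to_universe(self, toy_universe):
        fam = FocusFamily.from_id_sets(toy_universe, [[1, 2, 3, 4]])
        b = 3
        table = coherent_function(fam, (b,))
        for mask in range(16):
            s = frozenset(i for i in range(4) if mask >> i & 1)
            assert table(s) == max(0, b - (4 - len(s)))

    def test_coherence_sandwich(self, rng):
        """For S ⊆ T the coherent bound obeys d(S) <= d(T) <= d(S)+|T\\S|."""
        for _ in range(20):
            family, oracles, alpha = random_instance(rng, "table")
            w = family.universe.size
            if w > 8:
                continue
            state = holm_partial_bounds(family, oracles, alpha)
            table = coherent_function(family, state.bounds)
            vals = table.values
            for t_mask in range(1 << w):
                for b in range(w):
                    if t_mask >> b & 1:
                        s_mask = t_mask ^ (1 << b)
                        assert vals[s_mask] <= vals[t_mask] <= vals[s_mask] + 1

    def test_bound_table_interface(self, toy_universe, toy_family, toy_bounds):
        queries = [_idx(toy_universe, [2, 3]), _idx(toy_universe, [2, 4])]
        table = coherent_bounds(toy_family, toy_bounds, queries=queries, alpha=0.05)
        assert table[queries[0]] == 1
        assert table.tdp(queries[1]) == 1.0


class TestGreedy:
    def test_toy_nonfocus_set(self, toy_universe, toy_family, toy_bounds):
        assert greedy_bound(toy_family, toy_bounds, _idx(toy_universe, [2, 3])) == 1

    def test_disjoint_query_is_zero(self, toy_universe, toy_family, toy_bounds):
        assert greedy_bound(toy_family, toy_bounds, _idx(toy_universe, [3])) == 0

    def test_never_exceeds_coherent_and_covers_focus_sets(self, rng):
        for _ in range(60):
            family, oracles, alpha = random_instance(rng, "table")
            w = family.universe.size
            state = holm_partial_bounds(family, oracles, alpha)
            table = coherent_function(family, state.bounds)
            masks = (
                range(1 << w)
                if w <= 8
                else rng.integers(0, 1 << w, size=128).tolist()
            )
            for mask in masks:
                s = frozenset(i for i in range(w) if int(mask) >> i & 1)
                assert greedy_bound(family, state.bounds, s) <= table(s)
            for i, focus in enumerate(family.members):
                assert greedy_bound(family, state.bounds, focus) >= state.bounds[i]


class TestComputeBounds:
    def test_end_to_end_holm_greedy(self, toy_family, toy_oracles, toy_universe):
        queries = [_idx(toy_universe, ids) for ids in ([2, 3], [2, 4], [1, 3])]
        table, state = compute_bounds(
            toy_family, toy_oracles, 0.05, queries, method="holm", mode="greedy"
        )
        assert state is not None
        assert [table[q] for q in queries] == [1, 2, 0]

    def test_bonferroni_exact_matches_coherent(
        self, toy_family, toy_oracles, toy_universe, toy_table
    ):
        queries = [_idx(toy_universe, ids) for ids in toy_table]
        table, state = compute_bounds(
            toy_family, toy_oracles, 0.05, queries, method="bonferroni", mode="exact"
        )
        assert state is None
        for ids, (_, _, e2) in toy_table.items():
            assert table[_idx(toy_universe, ids)] == e2

    def test_unknown_options_rejected(self, toy_family, toy_oracles):
        with pytest.raises(ValueError, match="method"):
            compute_bounds(toy_family, toy_oracles, 0.05, [], method="x")
        with pytest.raises(ValueError, match="mode"):
            compute_bounds(toy_family, toy_oracles, 0.05, [], mode="x")
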