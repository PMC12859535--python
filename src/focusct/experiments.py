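"""Simulation harnesses: coverage checks and the focused-power comparison.

These drive the synthetic generators through the full pipeline and are shared
by the test suite, the acceptance script and the ``focusct simulate`` CLI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .combine import greedy_bound
from .local_tests import two_sample_t_pvalues
from .partial import fisher_partial_oracles, fisher_subset_bound, holm_partial_bounds
from .synthetic import (
    _alpha_hat_batch,
    _rng,
    gen_dyadic_tree,
    gen_focus_structure,
    gen_two_group,
)

__all__ = [
    "coverage_two_group",
    "adafilter_fwer",
    "focused_power",
    "tree_experiment",
]


def mc_se(rate: float, reps: int) -> float:
    """Monte Carlo standard error of a binomial rate estimate."""
    return float(np.sqrt(rate * (1 - rate) / reps))


def coverage_two_group(
    reps: int = 2000,
    seed=None,
    n: int = 50,
    w: int = 10,
    m: int = 3,
    set_size: int = 4,
    signal_prop: float = 0.0,
    mu: float = 0.7,
    alpha: float = 0.05,
    tdp_grid=None,
) -> dict:
    """Simultaneous coverage of the combined procedure on two-group data.

    The coverage event over *all* 2^w query sets reduces to the local test
    at the true-null set: every bound d̄(S) is ≤ |S ∩ W₁| for all S iff
    φ̄(W₀) = 0, i.e. iff no focus set claims more discoveries than it truly
    holds (d_i^{α/h}(F_i) ≤ |F_i ∩ W₁| for all i).  The per-rep error
    indicator is computed through that reduction, which is itself verified
    exhaustively in the test suite.
    """
    rng = _rng(seed)
    if tdp_grid is None:
        tdp_grid = [0.0] if signal_prop == 0 else [0.0, 0.5, 1.0]
    errors = 0
    for _ in range(reps):
        X, y, truth = gen_two_group(
            n=n, w=w, signal_prop=signal_prop, mu=mu, seed=rng
        )
        structure = gen_focus_structure(
            truth,
            n_focus=m,
            n_nonfocus=0,
            tdp_grid=tdp_grid,
            set_size=set_size,
            overlap=0.3,
            seed=rng,
        )
        family = structure.family
        pvals = two_sample_t_pvalues(X, y)
        oracles = fisher_partial_oracles(family, pvals)
        state = holm_partial_bounds(family, oracles, alpha)
        w1 = truth.w1
        if any(
            d > len(f & w1) for d, f in zip(state.bounds, family.members)
        ):
            errors += 1
    rate = errors / reps
    return {
        "reps": reps,
        "error_rate": rate,
        "alpha": alpha,
        "mc_se": mc_se(alpha, reps),
    }


def adafilter_fwer(
    reps: int = 2000,
    seed=None,
    m: int = 20,
    v: int = 4,
    r: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error rate of AdaFilter-r on fully null uniform matrices."""
    rng = _rng(seed)
    P = rng.uniform(size=(reps, m, v))
    sp = np.sort(P, axis=2)
    R = (v - r + 1) * sp[:, :, r - 2]
    S = (v - r + 1) * sp[:, :, r - 1]
    ah = _alpha_hat_batch(R, alpha)
    any_rejection = (S < ah[:, None]).any(axis=1)
    rate = float(any_rejection.mean())
    return {
        "reps": reps,
        "error_rate": rate,
        "alpha": alpha,
        "mc_se": mc_se(alpha, reps),
    }


def focused_power(
    reps: int = 100,
    seed=None,
    n: int = 100,
    w: int = 200,
    signal_prop: float = 0.5,
    mu: float = 0.7,
    set_size: int = 20,
    n_focus: int = 11,
    n_nonfocus: int = 11,
    overlap: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combined (focused) procedure vs. full Fisher closed testing.

    Per replication: two-group data, per-feature t-test p-values, 11 focus
    and 11 nonfocus sets with realised TDP on the grid 0..1.  The combined
    arm runs Fisher partial closed testing per focus set, combines by Holm
    and answers every set with the greedy shortcut; the comparator computes
    the exact full closed-testing bound with Fisher local tests for the same
    sets.  Returns mean bound and mean TDP bound per set type and arm.
    """
    rng = _rng(seed)
    acc = {
        ("focus", "combined"): [],
        ("focus", "full_ct"): [],
        ("nonfocus", "combined"): [],
        ("nonfocus", "full_ct"): [],
    }
    for _ in range(reps):
        X, y, truth = gen_two_group(
            n=n, w=w, signal_prop=signal_prop, mu=mu, seed=rng
        )
        structure = gen_focus_structure(
            truth,
            n_focus=n_focus,
            n_nonfocus=n_nonfocus,
            set_size=set_size,
            overlap=overlap,
            seed=rng,
        )
        family = structure.family
        pvals = two_sample_t_pvalues(X, y)
        oracles = fisher_partial_oracles(family, pvals)
        state = holm_partial_bounds(family, oracles, alpha)
        for name, members, tdp, is_focus in structure.all_sets():
            combined = greedy_bound(family, state.bounds, members)
            full_ct = fisher_subset_bound(pvals, sorted(members), alpha)
            key = "focus" if is_focus else "nonfocus"
            acc[(key, "combined")].append(combined / len(members))
            acc[(key, "full_ct")].append(full_ct / len(members))
    rows = []
    for (set_type, arm), values in acc.items():
        rows.append(
            {
                "set_type": set_type,
                "arm": arm,
                "mean_tdp_bound": float(np.mean(values)),
                "n_sets": len(values),
            }
        )
    return pd.DataFrame(rows)


def tree_experiment(
    reps: int = 100,
    seed=None,
    n_leaves: int = 128,
    signal_prop: float = 0.5,
    placement: str = "grouped",
    mu: float = 4.0,
    alpha: float = 0.05,
    layer: int = 4,
) -> pd.DataFrame:
    """Tree-structured focus families: node sets at one layer vs. all nodes.

    For each replication a dyadic tree of leaf hypotheses is drawn; the
    combined procedure is run once with the nodes of ``layer`` as focus sets
    and once with every node of the tree, and the greedy bound is evaluated
    at the (post hoc) set of all true signal leaves.  Reports the mean TDP
    bound per arm.
    """
    rng = _rng(seed)
    acc = {f"ptd@{layer}": [], "ptd@all": []}
    for _ in range(reps):
        tree = gen_dyadic_tree(
            n_leaves=n_leaves,
            signal_prop=signal_prop,
            placement=placement,
            mu=mu,
            seed=rng,
        )
        target = tree.truth.w1
        if not target:
            continue
        for arm, family in (
            (f"ptd@{layer}", tree.family_at_layer(layer)),
            ("ptd@all", tree.family_all_nodes()),
        ):
            oracles = fisher_partial_oracles(family, tree.pvalues)
            state = holm_partial_bounds(family, oracles, alpha)
            bound = greedy_bound(family, state.bounds, target)
            acc[arm].append(bound / len(target))
    return pd.DataFrame(
        [
            {"arm": arm, "mean_tdp_bound": float(np.mean(v)), "reps": len(v)}
            for arm, v in acc.items()
        ]
    )
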