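"""Seeded generators for the simulation designs used throughout the package.

Three designs are emulated:

* two-group normal features with a binary response (n=100 samples, w=1000
  features, signal mean 0.7 in one group, σ=1) feeding per-feature t-tests;
* focus/nonfocus set structures with prescribed, exactly realised TDP on a
  grid 0, 0.1, ..., 1, with configurable set size and overlap;
* m×v replicability p-value matrices (m=10 features, v=10 studies) with
  Beta(a, 1) signal p-values and Uniform(0,1) nulls, plus a summary grid of
  mean replicability bounds over v1 = 0..v.

All generators are pure functions of their configuration and seed, and every
generator also returns the ground-truth assignment so coverage tests can
compare bounds against the realised number of true discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .family import FeatureUniverse, FocusFamily
from .replicability import PValueMatrix, adafilter, feature_bounds

__all__ = [
    "TruthAssignment",
    "FocusStructure",
    "DyadicTree",
    "gen_two_group",
    "gen_focus_structure",
    "gen_pc_matrix",
    "gen_dyadic_tree",
    "replicability_grid",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TruthAssignment:
    """Ground truth: which features are true signals (members of W₁)."""

    signal: np.ndarray  # boolean, length w

    @property
    def w1(self) -> frozenset[int]:
        return frozenset(np.nonzero(self.signal)[0].tolist())

    def true_discoveries(self, s) -> int:
        return len(frozenset(s) & self.w1)


def gen_two_group(
    n: int = 100,
    w: int = 1000,
    signal_prop: float = 0.2,
    mu: float = 0.7,
    sigma: float = 1.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, TruthAssignment]:
    """Two-group design: binary response, normal features, mean shift mu.

    The response is Bernoulli(0.5); features are independent N(0, σ²) and the
    truly associated features get mean ``mu`` in the response-1 group.
    Returns (n×w feature matrix, response, truth).
    """
    rng = _rng(seed)
    y = rng.integers(0, 2, size=n)
    while y.min() == y.max():  # both groups must be nonempty
        y = rng.integers(0, 2, size=n)
    n_signal = int(round(signal_prop * w))
    signal = np.zeros(w, dtype=bool)
    signal[rng.choice(w, size=n_signal, replace=False)] = True
    X = rng.normal(0.0, sigma, size=(n, w))
    X[np.ix_(y == 1, signal)] += mu
    return X, y, TruthAssignment(signal=signal)


@dataclass
class FocusStructure:
    """Focus family plus post-hoc query sets with known realised TDP."""

    family: FocusFamily
    focus_tdp: tuple[float, ...]
    nonfocus_sets: tuple[frozenset[int], ...]
    nonfocus_tdp: tuple[float, ...]

    def all_sets(self) -> list[tuple[str, frozenset[int], float, bool]]:
        """(name, members, realised tdp, is_focus) for every set."""
        out = [
            (name, members, tdp, True)
            for name, members, tdp in zip(
                self.family.names, self.family.members, self.focus_tdp
            )
        ]
        out += [
            (f"N{j + 1}", s, tdp, False)
            for j, (s, tdp) in enumerate(zip(self.nonfocus_sets, self.nonfocus_tdp))
        ]
        return out


def _draw_set(
    rng: np.random.Generator,
    k_signal: int,
    k_null: int,
    signal_pool: np.ndarray,
    null_pool: np.ndarray,
    used_signal: set[int],
    used_null: set[int],
    overlap: float,
) -> frozenset[int]:
    """Draw a set with exactly k_signal signals, reusing a fraction of
    already-used features to create overlap between sets."""
    members: set[int] = set()
    for k, pool, used in (
        (k_signal, signal_pool, used_signal),
        (k_null, null_pool, used_null),
    ):
        if k == 0:
            continue
        reusable = np.array(sorted(used), dtype=int)
        fresh = np.setdiff1d(pool, reusable, assume_unique=False)
        n_reuse = min(int(round(overlap * k)), reusable.size)
        n_fresh = k - n_reuse
        if n_fresh > fresh.size:  # fall back on reuse when fresh pool is dry
            n_reuse = min(k - fresh.size, reusable.size)
            n_fresh = k - n_reuse
        if n_fresh > fresh.size or n_reuse > reusable.size:
            raise ValueError(
                f"cannot realise a set with {k} features from a pool of "
                f"{pool.size}"
            )
        chosen = []
        if n_reuse:
            chosen.append(rng.choice(reusable, size=n_reuse, replace=False))
        if n_fresh:
            chosen.append(rng.choice(fresh, size=n_fresh, replace=False))
        picked = np.concatenate(chosen) if chosen else np.array([], dtype=int)
        used.update(int(x) for x in picked)
        members.update(int(x) for x in picked)
    return frozenset(members)


def gen_focus_structure(
    truth: TruthAssignment,
    n_focus: int = 11,
    n_nonfocus: int = 11,
    tdp_grid: Sequence[float] | None = None,
    set_size: int = 10,
    overlap: float = 0.3,
    seed=None,
) -> FocusStructure:
    """Focus and nonfocus sets with exactly realised TDP on a grid.

    Each set holds ``set_size`` features of which exactly
    ``tdp * set_size`` are true signals (must be an integer, else an error).
    ``overlap`` is the target fraction of each set drawn from features
    already used by earlier sets, so focus sets overlap each other and the
    nonfocus sets.
    """
    rng = _rng(seed)
    if tdp_grid is None:
        tdp_grid = np.round(np.linspace(0.0, 1.0, 11), 10)
    tdp_focus = list(tdp_grid)[:n_focus]
    if len(tdp_focus) < n_focus:
        tdp_focus = (tdp_focus * n_focus)[:n_focus]
    tdp_nonfocus = list(tdp_grid)[:n_nonfocus]
    if len(tdp_nonfocus) < n_nonfocus:
        tdp_nonfocus = (tdp_nonfocus * n_nonfocus)[:n_nonfocus]

    signal_pool = np.nonzero(truth.signal)[0]
    null_pool = np.nonzero(~truth.signal)[0]
    used_signal: set[int] = set()
    used_null: set[int] = set()

    def realise(tdp: float) -> frozenset[int]:
        k_signal = tdp * set_size
        if abs(k_signal - round(k_signal)) > 1e-9:
            raise ValueError(
                f"TDP {tdp} not realisable exactly at set size {set_size}"
            )
        k_signal = int(round(k_signal))
        return _draw_set(
            rng,
            k_signal,
            set_size - k_signal,
            signal_pool,
            null_pool,
            used_signal,
            used_null,
            overlap,
        )

    focus_sets = [realise(t) for t in tdp_focus]
    nonfocus_sets = [realise(t) for t in tdp_nonfocus]
    universe = FeatureUniverse(range(truth.signal.size))
    family = FocusFamily(universe, tuple(focus_sets))
    return FocusStructure(
        family=family,
        focus_tdp=tuple(float(t) for t in tdp_focus),
        nonfocus_sets=tuple(nonfocus_sets),
        nonfocus_tdp=tuple(float(t) for t in tdp_nonfocus),
    )


def gen_pc_matrix(
    v1: int,
    m: int = 10,
    v: int = 10,
    beta_shape: float = 0.05,
    seed=None,
) -> tuple[PValueMatrix, np.ndarray]:
    """Replicability p-value matrix: Beta(a,1) signals, Uniform(0,1) nulls.

    The first half of the features carry signal in ``v1`` of the v studies;
    the second half are fully null.  Returns the matrix and the per-row
    count of signal studies.
    """
    rng = _rng(seed)
    if not (0 <= v1 <= v):
        raise ValueError(f"v1 must be in [0, {v}]")
    P = rng.uniform(size=(m, v))
    half = m // 2
    counts = np.zeros(m, dtype=np.int64)
    if v1 > 0:
        P[:half, :v1] = rng.beta(beta_shape, 1.0, size=(half, v1))
        counts[:half] = v1
    return PValueMatrix(P), counts


@dataclass
class DyadicTree:
    """Complete dyadic tree over leaf hypotheses with per-layer node sets."""

    pvalues: np.ndarray
    truth: TruthAssignment
    n_layers: int
    node_sets: dict[int, tuple[frozenset[int], ...]] = field(default_factory=dict)

    def family_at_layer(self, layer: int) -> FocusFamily:
        universe = FeatureUniverse(range(self.pvalues.size))
        return FocusFamily(universe, self.node_sets[layer])

    def family_all_nodes(self) -> FocusFamily:
        universe = FeatureUniverse(range(self.pvalues.size))
        members = tuple(
            s for layer in sorted(self.node_sets) for s in self.node_sets[layer]
        )
        return FocusFamily(universe, members)


def gen_dyadic_tree(
    n_leaves: int = 128,
    signal_prop: float = 0.5,
    placement: str = "grouped",
    mu: float = 1.0,
    truncate_to: int | None = None,
    seed=None,
) -> DyadicTree:
    """Tree-structured hypotheses: leaf z-scores N(mu·signal, 1), one-sided p.

    A complete dyadic tree over ``n_leaves`` (a power of two) has
    log2(n_leaves)+1 layers; layer 1 is the root, the last layer the
    singleton leaves.  ``placement``: 'grouped' puts the signal leaves in one
    contiguous branch, 'random' scatters them.  ``truncate_to`` keeps only
    the first k leaves (node sets intersected, empties dropped), matching
    designs stated for non-power-of-two element counts.
    """
    rng = _rng(seed)
    n_layers = int(np.log2(n_leaves)) + 1
    if 2 ** (n_layers - 1) != n_leaves:
        raise ValueError("n_leaves must be a power of two")
    n_signal = int(round(signal_prop * n_leaves))
    signal = np.zeros(n_leaves, dtype=bool)
    if placement == "grouped":
        signal[:n_signal] = True
    elif placement == "random":
        signal[rng.choice(n_leaves, size=n_signal, replace=False)] = True
    else:
        raise ValueError("placement must be 'grouped' or 'random'")
    z = rng.normal(0.0, 1.0, size=n_leaves) + mu * signal
    p = stats.norm.sf(z)

    keep = n_leaves if truncate_to is None else int(truncate_to)
    node_sets: dict[int, tuple[frozenset[int], ...]] = {}
    for layer in range(1, n_layers + 1):
        n_nodes = 2 ** (layer - 1)
        width = n_leaves // n_nodes
        sets = []
        for j in range(n_nodes):
            members = frozenset(
                range(j * width, min((j + 1) * width, keep))
            ) & frozenset(range(keep))
            if members:
                sets.append(members)
        node_sets[layer] = tuple(sets)
    return DyadicTree(
        pvalues=p[:keep],
        truth=TruthAssignment(signal=signal[:keep]),
        n_layers=n_layers,
        node_sets=node_sets,
    )


def _alpha_hat_batch(R: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorised AdaFilter α̂ over a batch of R-vectors (reps × m)."""
    reps, m = R.shape
    cand = np.concatenate(
        [
            np.full((reps, 1), alpha),
            np.broadcast_to(alpha / np.arange(1, m + 1), (reps, m)).copy(),
            np.clip(R, 0.0, alpha),
        ],
        axis=1,
    )
    counts = (R[:, None, :] < cand[:, :, None]).sum(axis=2)
    feasible = cand * counts <= alpha
    return np.where(feasible, cand, 0.0).max(axis=1)


def replicability_grid(
    reps: int = 1000,
    seed=None,
    alpha: float = 0.05,
    m: int = 10,
    v: int = 10,
    beta_shape: float = 0.05,
) -> pd.DataFrame:
    """Mean replicability bounds over v1 = 0..v for partial CT and AdaFilter-r.

    For each v1, ``reps`` matrices are generated (first half of features with
    v1 signal studies, second half null); the table reports the mean bound
    over features and replications for partial closed testing at α/m and for
    AdaFilter-r, r = 2..v, alongside the true mean number of signal studies
    v1/2.
    """
    rng = _rng(seed)
    half = m // 2
    rows = {"true_mean": [], "partial_ct": []}
    for r in range(2, v + 1):
        rows[f"adafilter-{r}"] = []
    for v1 in range(v + 1):
        P = rng.uniform(size=(reps, m, v))
        if v1 > 0:
            P[:, :half, :v1] = rng.beta(beta_shape, 1.0, size=(reps, half, v1))
        rows["true_mean"].append(v1 / 2)
        flat = P.reshape(reps * m, v)
        pct = feature_bounds(flat, alpha / m)
        rows["partial_ct"].append(float(pct.mean()))
        sp = np.sort(P, axis=2)
        for r in range(2, v + 1):
            R = (v - r + 1) * sp[:, :, r - 2]
            S = (v - r + 1) * sp[:, :, r - 1]
            ah = _alpha_hat_batch(R, alpha)
            rejected = S < ah[:, None]
            rows[f"adafilter-{r}"].append(float(rejected.mean() * r))
    return pd.DataFrame(rows, index=range(v + 1)).T
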