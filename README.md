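# focusct

Simultaneous true-discovery-proportion (TDP) bounds that focus power on
feature sets you prespecify — with valid post-hoc inference for every other
set.

## The problem

In large-scale multiple testing (gene expression, GO categories, brain
imaging), a *true discovery guarantee* procedure returns, for any feature set
S, a lower confidence bound d(S) on the number of true signals in S, valid
simultaneously over **all** S ⊆ W at confidence 1−α:

    P( d(S) ≤ |S ∩ W₁|  for all S ⊆ W ) ≥ 1 − α,

where W₁ is the unknown set of false null hypotheses. Simultaneity means you
may choose S after seeing the data. Closed testing is the admissible way to
build such procedures, but a generic closed testing procedure spreads its
power over all 2^|W| sets.

`focusct` instead concentrates power on *focus sets* F₁, …, F_m chosen in
advance (pathways, GO terms, regions of interest). On each focus set a
*partial* procedure d_i — here closed testing with Fisher's combination local
test, restricted to 2^{F_i} — runs at level α/m (Bonferroni) or α/h, where
Holm's factor h shrinks as focus sets become fully rejected and their share
of α is recycled. Bounds for arbitrary post-hoc sets follow by
*interpolation*:

    d(S) ≥ d(U) − |U \ S| + d(S \ U)   for any U,

iterated to a fixpoint (the *coherent* procedure), or by a fast greedy
shortcut that credits focus sets one at a time in order of incremental
contribution and never exceeds the coherent bound. The whole construction is
a conservative shortcut to an explicit closed testing procedure with local
test

    φ̄(S) = 1  iff  d_i^{α/h}(F_i) > |F_i \ S|  for some i,

which the package also implements, as a verification oracle and to quantify
what the shortcuts give up.

The same machinery specialises to *replicability analysis*: with features as
disjoint focus sets over an m×v p-value matrix (rows = features, columns =
studies), partial closed testing yields per-feature lower bounds on the
number of studies in which the effect replicates, via partial-conjunction
Fisher tests; AdaFilter is included as the fixed-r comparator.

## Worked example

Four features W = {1,2,3,4}; focus sets F₁ = {1,2} with partial bound d₁ = 1
and F₂ = {2,4} with d₂ = 2:

```python
from focusct import FeatureUniverse, FocusFamily, greedy_bound
from focusct.combine import coherent_function, trivial_bounds, interpolate_once

universe = FeatureUniverse([1, 2, 3, 4])
family = FocusFamily.from_id_sets(universe, {"F1": [1, 2], "F2": [2, 4]})
coherent = coherent_function(family, (1, 2), mode="naive")
print(coherent(universe.indices_of([2, 3])))   # 1
```

`python examples/toy_bounds.py` prints:

```
set        d0  d1  coherent  greedy
{2}         0   1      1       1
{1, 2}      1   1      1       1
{2, 3}      0   1      1       1
{2, 4}      2   2      2       2
{1, 2, 4}   0   2      2       2
{1, 2, 3, 4}  0   2      2       2

interpolation converged after 2 sweeps
```

The trivial procedure d⁰ knows only the focus sets. One interpolation round
d¹ already proves a discovery in the post-hoc set {2,3}: F₂ certifies 2 true
discoveries and at most one of them (feature 4) lies outside {2,3}. A second
sweep confirms the fixpoint, which coincides with explicit closed testing on
this example, and the greedy shortcut loses nothing here.

The other `examples/*.py` scripts each exercise one capability: focused
gene-set bounds from simulated two-group data, the replicability table,
the focused-power trade-off, and the randomised lemma verification. A thin
CLI exposes the same functionality (`focusct bound`, `focusct replicate`,
`focusct verify`, `focusct simulate`).

## Repository layout

- `src/focusct/family.py` — feature universe, focus families, bound-oracle contracts
- `src/focusct/local_tests.py` — Fisher / Simes local tests, two-sample t p-values
- `src/focusct/partial.py` — partial closed testing per focus set; Bonferroni/Holm combination
- `src/focusct/combine.py` — trivial bounds, interpolation, coherent fixpoint, greedy shortcut
- `src/focusct/oracle.py` — explicit closed testing (φ, φ̃, φ̄) for verification
- `src/focusct/replicability.py` — partial-conjunction bounds, AdaFilter
- `src/focusct/synthetic.py`, `experiments.py` — seeded generators and simulation harnesses
- `src/focusct/verify.py` — randomised lemma suite
- `docs/methods.md` — models, assumptions, numerical choices, limitations
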