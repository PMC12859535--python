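# Methods

## Model and guarantee

Features s ∈ W carry null hypotheses H_s; W₀ is the set of true nulls,
W₁ = W \ W₀. A true discovery guarantee procedure d provides
P(d(S) ≤ |S ∩ W₁| for all S ∈ 2^W) ≥ 1 − α. Focus sets F₁…F_m are fixed
before seeing the data; they may overlap. On each F_i a *partial* procedure
d_i^γ gives the same guarantee restricted to 2^{F_i}.

Partial procedures here are closed testing within the focus set using
Fisher's combination local test: the intersection hypothesis over K is
rejected when −2 Σ_{j∈K} log p_j exceeds the χ²(2|K|) upper-γ quantile.
This assumes p-values that are independent (or at least that the Fisher
statistic is valid) within each focus set and marginally super-uniform under
the null. Any other partial procedure can be plugged in through the oracle
contract `(level, subset) → integer`, which must be monotone in the level
and satisfy the interpolation floor d(S) ≤ d(T) + |S\T| for T ⊆ S.

## Combination, interpolation, greedy shortcut

Per-focus bounds are taken at level α/m (Bonferroni) or α/h (Holm). Holm's
factor starts at h = m; any focus set with d_i^{α/h}(F_i) = |F_i| is moved to
the fully-rejected pool, h becomes the number of remaining sets, and the
remaining bounds are recomputed; sweeps repeat until nothing new is fully
rejected. Sets found fully rejected in one sweep are all removed before h is
updated once — processing order within a sweep therefore does not matter.
Stopping the iteration early (option `max_rounds`) is allowed and
conservative.

The trivial procedure d⁰ assigns d_i to F_i and 0 elsewhere (ties take the
maximum). Interpolation d'(S) = max_U d(U) − |U\S| + d(S\U) is iterated in
full sweeps until a sweep changes nothing; the resulting fixpoint is the
coherent procedure. Two exact evaluation modes exist: a naive sweep over all
U ∈ 2^W (default up to |W| = 12) and a sweep restricted to unions of focus
sets (up to |W| = 16); they agree on every instance tested and the
restriction is also validated against the closed-testing oracle below.

The greedy shortcut evaluates a query S without any lattice enumeration:
repeatedly pick the focus set maximising c_i = d_i − |F_i \ S'| over the
not-yet-credited part S' of S, credit c_i discoveries, remove F_i ∩ S' from
S', retire i; stop when no contribution is positive. Each credited batch
counts distinct discoveries, so the total is a valid lower bound and never
exceeds the coherent bound. Ties are broken by larger |F_i ∩ S'|, then lower
focus index, making the output deterministic; tie-breaking only affects
which of equally-valued certificates is used, not validity.

## Explicit closed testing and what the shortcuts give up

The package constructs three local tests over the full universe:
φ(S) rejects when some partial procedure finds a discovery in F_i ∩ S at
level α/m_S (m_S = number of focus sets meeting S); φ̃(S) uses only full-set
bounds, d_i^{α/m_S}(F_i) > |F_i \ S|; φ̄(S) uses the converged Holm bounds
d_i^{α/h}(F_i) > |F_i \ S|. Always φ̄ ≤ φ̃ ≤ φ, with φ̃ = φ when S splits
every focus set cleanly (F_i ∩ S ∈ {F_i, ∅}). φ̄ is monotone in S, so its
closure satisfies ψ̄ = φ̄ and its closed-testing bound is computable as
d̄(S) = |S| − max{|J| : J ⊆ S, |F_i ∩ J| ≤ |F_i| − d_i for all i}.

A finding worth flagging: the coherent interpolation fixpoint equals d̄ on
pairwise **disjoint** focus families (verified exhaustively on thousands of
randomised instances), but for **overlapping** families closed testing can
be strictly sharper. A concrete counterexample is frozen in the test suite:
three mutually overlapping focus sets over nine features where d̄(S) = 2
while the interpolation fixpoint — confirmed by an independent brute-force
implementation — gives 1. The reason is structural: interpolation chains
combine constraints pairwise and subtract overlap elements per step, while
the closed-testing certificate counts them jointly across all constraints.
The practical procedures (interpolation, greedy) are therefore *conservative*
shortcuts under overlap, never anti-conservative; users with heavily
overlapping focus sets pay a power price twice, once in the α/m split and
once in this interpolation gap.

ψ for the non-monotone variants is computed by a superset-OR transform over
the subset lattice (O(w·2^w)), and bounds by a subset-max transform, rather
than the naive 3^w superset scan. The oracle is capped at |W| = 16 and is a
verification surface, not the user path.

## Fast exact Fisher paths

Full-set bounds d_i^γ(F_i) use the sorted-suffix path: among size-k subsets
the hardest to reject holds the k largest p-values, so d = |F_i| − max
surviving k (O(n log n)). Arbitrary-subset bounds d_i^γ(S) use a
size-stratified argument: for a non-rejected candidate K with a = |K ∩ S|
and b = |K \ S| members, the minimal statistic takes the a largest p-values
inside S and the b largest outside; scanning the (a, b) grid gives the exact
bound in O(|S|·|W\S|) after sorting. Both are validated against brute-force
enumeration of the subset lattice on small instances. The same subset path
serves as the exact full closed-testing comparator in the focused-power
simulation. Boundary convention: rejection iff the Fisher p-value ≤ level
(statistic ≥ the χ² quantile); p-values of exactly 0 are clamped to 1e-300
with a warning before taking logs.

## Replicability analysis

For an m×v p-value matrix with per-row order statistics p_{(1)} ≤ … ≤
p_{(v)}, the partial conjunction p-value for "at least r of v studies show
the effect" is Fisher's combination of the v−r+1 largest p-values; r = 0 is
rejected by convention. The per-feature bound is d_i = max{r : the PC
p-value at u is ≤ α/m for every u ≤ r}. The sequence of PC p-values is not
monotone in r (dropping a large p-value can *lower* the Fisher combination
p-value because the degrees of freedom shrink — row (0.9, 0.9) is a
counterexample), which is exactly why the bound requires rejection at every
u ≤ r; the max-r characterisation coincides with brute-force closed testing
over the row, and the tests verify this. Treating rows as disjoint focus
sets, the Holm upgrade applies unchanged when some feature reaches d_i = v.

AdaFilter-r computes the filtering p-value R_i = (v−r+1) p_{(r−1)} and
selection p-value S_i = (v−r+1) p_{(r)}, and rejects when S_i < α̂ with
α̂ = sup{γ ∈ [0, α] : γ·#{R_i < γ} ≤ α}. The constraint function is
piecewise linear with jumps only at the R_i, so the supremum is attained on
the candidate grid {α} ∪ {α/k : k ≤ m} ∪ {R_i} (clipped to [0, α]); the
implementation evaluates exactly that grid and is checked against a dense
numeric search. Strict inequalities are used on both R_i < γ and S_i < α̂,
as in the defining formulas.

## Synthetic designs

* **Two-group**: n = 100 samples, w = 1000 features, binary response
  Bernoulli(0.5), independent N(0, 1) features, truly associated features
  shifted by μ = 0.7 in the response-1 group (the shift is placed in one
  group; only the group contrast matters for the t-test and this realises
  the stated association strength). P-values from the equal-variance
  two-sided two-sample t-test — equal variances hold by construction, and
  sidedness is configurable since either convention is defensible.
* **Focus structures**: 11 focus and 11 post-hoc sets with realised TDP
  exactly on the grid 0, 0.1, …, 1. Set size (default 10; 20 in the
  focused-power runs so that every grid value is an integer count) and the
  reuse fraction driving overlap (default 0.3) are exposed as knobs, since
  the construction details beyond "overlapping, TDP grid" are free
  parameters of the design.
* **Replicability matrices**: m = 10 features × v = 10 studies; the first
  half of the features carry signal in v1 studies, the rest none; signal
  p-values are Beta(a, 1) with a = 0.05 by default, nulls Uniform(0, 1).
  The Beta shape is exposed because the signal-strength-dependent summary
  cells depend on it directly; with a = 0.05 the *structure* of the summary
  table (null column at 0, AdaFilter-r saturating at r beyond its
  sweet spot, sub-diagonal zeros, partial CT monotone and dominating off
  the sweet spot) reproduces, while absolute signal-cell values shift with a.
* **Dyadic trees**: complete binary tree over 128 leaves (8 layers, root =
  layer 1), leaf z-scores N(μ·signal, 1), one-sided p-values; signals either
  grouped in one branch or scattered. An option truncates to the first k
  leaves for non-power-of-two designs (a "complete dyadic tree with 100
  elements" is not realisable without truncation). Node sets of any layer,
  or all nodes, serve as focus families.

These generators emulate independent, exactly-normal features with known
truth; they do not model correlated features, heavy tails, or data-driven
focus-set selection, so passing tests certify the procedures' error control
and orderings under the stated designs, not robustness to dependence.

## Simulation sizes and checks

Coverage checks use the exact reduction: every bound d̄(S) ≤ |S ∩ W₁| for
all 2^w sets simultaneously iff φ̄(W₀) = 0, i.e. iff no focus set claims
more than |F_i ∩ W₁|; the reduction itself is verified exhaustively on small
instances. Monte Carlo sizes: 2000 replications for coverage/FWER checks
(threshold α + 3·SE), 1000 replications for the replicability summary
table, 100 replications at w = 200 for the focused-power comparison, and
~2400 randomised instances for the lemma suite — sizes chosen to keep the
full suite in the tens of seconds while leaving Monte Carlo error well below
the margins being tested.

## Known limitations

* The general-purpose branch-and-bound for arbitrary-subset queries of
  sum-based tests is not implemented; arbitrary subsets are exact for Fisher
  via the size-stratified path, and other local tests fall back on
  enumeration (focus sets ≤ 20 features).
* The exact coherent fixpoint is limited to enumerable universes
  (|W| ≤ 16); larger problems use the greedy shortcut, which is
  conservative.
* Focus sets must be chosen independently of the data; nothing in the
  package checks this.
* AdaFilter validity assumes all m×v p-values independent; dependence-robust
  variants are out of scope.
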