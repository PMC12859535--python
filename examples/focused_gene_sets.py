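"""Focused TDP bounds from a two-group study with gene-set focus sets.

Simulates a case/control study (100 samples, 200 genes, half truly
associated with mean shift 0.7), computes per-gene t-test p-values, runs
Fisher partial closed testing on 11 prespecified focus sets combined by
Holm's procedure, and answers both the focus sets and 11 post-hoc query
sets with the greedy shortcut.  TDP = (lower bound on true discoveries) /
set size; realised TDP is known here because the data are simulated.
"""

from focusct import (
    fisher_partial_oracles,
    greedy_bound,
    holm_partial_bounds,
    two_sample_t_pvalues,
)
from focusct.synthetic import gen_focus_structure, gen_two_group

X, y, truth = gen_two_group(n=100, w=200, signal_prop=0.5, mu=0.7, seed=1)
structure = gen_focus_structure(truth, set_size=20, overlap=0.3, seed=2)
family = structure.family

pvals = two_sample_t_pvalues(X, y)
oracles = fisher_partial_oracles(family, pvals)
state = holm_partial_bounds(family, oracles, alpha=0.05)
print(f"Holm factor after convergence: h = {state.h} of m = {family.m}")

print("\nset   type      true TDP   TDP bound")
for name, members, tdp, is_focus in structure.all_sets():
    bound = greedy_bound(family, state.bounds, members)
    kind = "focus" if is_focus else "post-hoc"
    print(f"{name:5s} {kind:9s} {tdp:8.1f} {bound / len(members):11.2f}")
print(
    "\nBounds hold simultaneously over all sets with 95% confidence:\n"
    "each set of 20 genes contains at least bound*20 true associations."
)
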