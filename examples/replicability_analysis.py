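"""Replicability: how many studies replicate each feature's effect?

Simulates a 10-feature x 10-study p-value matrix where the first five
features carry signal in six studies each, then compares the partial
closed-testing bound (simultaneous over all r) with AdaFilter at fixed
r = 2 and r = 6.
"""

import numpy as np

from focusct.replicability import adafilter, replicability_table
from focusct.synthetic import gen_pc_matrix

matrix, signal_counts = gen_pc_matrix(v1=6, m=10, v=10, beta_shape=0.05, seed=4)

pct = replicability_table(matrix, alpha=0.05, method="partial_ct")
ada2 = adafilter(matrix, r=2, alpha=0.05)
ada6 = adafilter(matrix, r=6, alpha=0.05)

print("feature      true  partialCT  AdaFilter-2  AdaFilter-6")
for i in range(matrix.m):
    print(
        f"{matrix.feature_ids[i]:12s} {signal_counts[i]:4d} {pct.bounds[i]:9d} "
        f"{ada2.bounds[i]:12d} {ada6.bounds[i]:12d}"
    )
print(f"\nAdaFilter adaptive levels: r=2 -> {ada2.alpha_hat:.4f}, r=6 -> {ada6.alpha_hat:.4f}")
print(
    "\nReading: partial closed testing certifies, per feature and with 95%\n"
    "simultaneous confidence, a lower bound on the number of replicating\n"
    "studies; AdaFilter-r only answers 'at least r or nothing' for its\n"
    "prespecified r."
)
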