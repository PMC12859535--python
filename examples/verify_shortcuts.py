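"""Verify the shortcut lemmas on randomised enumerable instances.

Draws 200 small random instances (mixed tabulated and Fisher partial
closed-testing oracles, overlapping and disjoint families) and checks every
ordering/equality relation tying the combined procedure to explicit closed
testing.  All violation counts must be zero.
"""

from focusct.verify import run_lemma_suite

result = run_lemma_suite(seed=0, n_instances=200)
print(result.summary())
print(
    "\nReading: 'ok' means the relation held on every instance; e.g. the\n"
    "greedy bound never exceeded the coherent bound, and the coherent bound\n"
    "never exceeded the explicit closed-testing bound."
)
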