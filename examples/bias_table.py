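"""Bias and CI coverage of case-only estimates across confounding regimes.

Runs a reduced version of the four-scenario study (100 replicates instead
of 500) and prints the summary table: mean case-only coefficient (mean
model SE) and the percentage of replicate 95% CIs containing the truth,
for the incidence-only variant A (truth 0) and the shared factor C
(truth 0.1).
"""

import collidersim as cs

report = cs.run_table1(seed=1, n_replicates=100)
print(report.to_markdown())
print()
print("Reading the table: A acquires a spurious negative effect that grows")
print("with unmeasured confounding, while C's true effect of 0.1 is")
print("attenuated toward the null; coverage of the truth collapses in both")
print("rows as confounding strengthens.")
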