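"""Per-group sample size for an RNA-seq differential-expression study.

Two groups are compared gene-by-gene under a negative-binomial read-count
model.  1% of 10,000 genes change 2.7-fold; every gene has an average read
depth of 5 and a coefficient of variation of 0.6.  Power per gene follows
the normal approximation for the Wald test of the log fold change.
"""

import numpy as np

from fdrpower import n_fdr_negbin

log_fc = np.log(np.repeat([1.0, 2.7], [9900, 100]))  # natural-log fold change
res = n_fdr_negbin(fdr=0.1, pwr=0.8, log_fc=log_fc, mu=5.0, sigma=0.6, pi0_method="BH")

print(f"subjects per group: {res.n}")
print(f"average power: {res.computed_avepow:.7g}")
print(f"fixed p-value threshold: {res.alpha:.7g}")

# 20 subjects per group give ~80.9% average power over the 100 changed
# genes at BH FDR 10%.  Note the power formula is asymptotic: for small n
# it can be optimistic, so double-check a final design by simulation
# (see validate_design_by_simulation.py).
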