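"""How many events does a prognostic-gene screen need?

A clinical trial will test each of 10,000 genes for association with
progression-free survival using single-predictor Cox regression.  1% of
genes are expected to carry a hazard ratio of 2 per unit of (unit-variance)
expression.  Cox power is driven by the number of observed events, not the
number of enrolled patients, so the design unit here is events.
"""

import numpy as np

from fdrpower import n_fdr_coxph

log_hr = np.log(np.repeat([1.0, 2.0], [9900, 100]))  # per-gene log hazard ratio
res = n_fdr_coxph(fdr=0.1, pwr=0.8, log_hr=log_hr, v=1.0, pi0_method="BH")

print(f"events needed: {res.n}")
print(f"average power at that event count: {res.computed_avepow:.7g}")
print(f"fixed p-value threshold: {res.alpha:.7g}")

# 37 events give ~81.4% average power over the 100 prognostic genes while
# BH controls the FDR at 10%.  Enrollment must then be sized (with accrual
# and follow-up assumptions) so that ~37 progressions or deaths are observed.
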