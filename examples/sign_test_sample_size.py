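"""Smallest sample size for a study of 10,000 sign tests.

Each subject contributes 10,000 binary readouts; each readout is tested
against a success probability of 0.5 with the sign test.  100 readouts
have a true success probability of 0.8, the other 9,900 are null
(pi0 = 0.99).  We want 80% average power over the 100 real effects while
the Benjamini-Hochberg procedure controls the FDR at 10%.
"""

import numpy as np

from fdrpower import n_fdr_signtest

theta = np.repeat([0.8, 0.5], [100, 9900])  # 100 non-null; 9,900 null
res = n_fdr_signtest(fdr=0.1, pwr=0.8, theta=theta, pi0_method="BH")

for key, value in res.to_dict().items():
    print(f"{key}: {value}")

# n: 45 subjects suffice; computed.avepow: ~0.810 is the average power the
# 100 non-null readouts actually attain at that n; alpha: ~0.00089 is the
# fixed unadjusted p-value cutoff the design implies; n0/n1 are the final
# search brackets and n.its the number of average-power evaluations the
# doubling + bisection search spent.
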