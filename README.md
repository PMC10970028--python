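# fdrpower

Power and sample-size calculations for studies that test thousands of
features at once — gene-expression screens, prognostic-marker scans,
RNA-seq differential expression — and declare significance with the false
discovery rate (FDR).

## The problem and the model

A study performs m hypothesis tests, a proportion π₀ of which have a true
null.  Applying a common unadjusted p-value threshold α to every test, the
FDR is well approximated by

    τ̃(α) = π̃₀ α / ( π₀ α + (1 − π₀)(1 − β) )

where 1 − β is the *average power* of the tests with a false null and π̃₀
is the operational value of π₀ the FDR procedure uses.  Setting τ̃(α) equal
to a target τ and solving for α gives the fixed p-value threshold the
design must power:

| convention | operational π̃₀ | solution |
|---|---|---|
| `JUNG` | π₀ (oracle) | α = τ(1−π₀)(1−β) / (π₀(1−τ)) |
| `BH`   | 1 (Benjamini–Hochberg step-up) | α = τ(1−π₀)(1−β) / (1−τπ₀) |
| `HH`   | π₀ + (1−π₀)β/(1−α) (histogram height near p = 1) | quadratic in α |
| `HM`   | π₀ + (1−π₀)(α+β) (twice the mean p-value) | quadratic in α |

The HH and HM forms come from a three-rectangle approximation of the
p-value histogram (uniform null mass π₀; a tall rectangle of true-positive
mass (1−π₀)(1−β) on [0, α); a type-II rectangle of mass (1−π₀)β on [α, 1])
and account for procedures that estimate π₀ from the data.  The solved α
is then fed to a per-test power formula — eleven test families are
supported, from sign tests through noncentral-t/F, exact Fisher and
Poisson tests, negative-binomial RNA-seq comparisons, and Cox regression —
and a doubling + bisection search returns the smallest sample size (or
event count, for Cox) whose average power over the false-null features
reaches 1 − β.

## Worked example

100 of 10,000 binary readouts per subject have a true success probability
of 0.8 (the rest are null at 0.5); we want 80% average power at BH FDR 10%:

```python
import numpy as np
from fdrpower import n_fdr_signtest

theta = np.repeat([0.8, 0.5], [100, 9900])
res = n_fdr_signtest(fdr=0.1, pwr=0.8, theta=theta, pi0_method="BH")
print(res.n, round(res.computed_avepow, 7), round(res.alpha, 10))
```

prints

```
45 0.8095842 0.0008879023
```

meaning: 45 subjects suffice; at that n the 100 real effects are detected
with 81.0% average power, and the design implies a fixed unadjusted
p-value cutoff of about 0.00089.  The `examples/` directory has one short
script per capability: threshold solving, sign-test/Cox/RNA-seq sample
sizes, the FDR-vs-power tradeoff table, and Monte-Carlo validation of a
design.  A thin CLI mirrors the library:

```sh
fdrpower alpha --method bh --fdr 0.1 --power 0.8 --pi0 0.99
fdrpower n --family sign --effects design.tsv --fdr 0.1 --power 0.8
```

where `design.tsv` lists per-feature effects with an optional `count`
column (`theta  count` / `0.8  100` / `0.5  9900`).

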