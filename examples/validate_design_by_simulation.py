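"""Double-check a designed study by Monte-Carlo simulation.

Analytic design calculations rest on the accuracy of each family's power
formula at the tiny p-value thresholds FDR control requires.  This script
designs a two-sample-t study, then simulates full experiments (draw data,
test every feature, apply Benjamini-Hochberg) to verify the realized FDR
and average power.
"""

import numpy as np

from fdrpower import DesignGoal, EffectProfile, find_sample_size, simulate_experiment

profile = EffectProfile.two_sample_t(np.repeat([0.0, 2.0], [190, 10]))
goal = DesignGoal(fdr=0.1, avg_power=0.8, pi0=profile.pi0, method="BH")
res = find_sample_size(goal, profile)
print(f"designed n = {res.n}/group, analytic average power = {res.computed_avepow:.4f}")

rep = simulate_experiment(profile, res.n, tau=0.1, reps=1000, seed=42,
                          analytic_alpha=res.alpha)
print(f"simulated power = {rep.mean_power:.4f} +/- {rep.se_power:.4f}")
print(f"simulated FDR   = {rep.mean_fdr:.4f} +/- {rep.se_fdr:.4f}  (target 0.1)")
print(f"mean realized BH cutoff = {rep.mean_realized_alpha:.5g} "
      f"(analytic alpha = {rep.analytic_alpha:.5g})")

# For exact-power families (t, F, Fisher, exact Poisson) the simulated
# numbers land within Monte-Carlo error of the analytic design.  For the
# normal-approximation families (sign, Cox, negative binomial, two
# proportions) the same harness will expose any shortfall - rerun it with
# the corresponding profile before committing to a study size.
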