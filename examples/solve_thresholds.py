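"""Solve the fixed p-value threshold for an FDR-controlled study, four ways.

A screen of 10,000 genes expects 1% of them (pi0 = 0.99) to respond to
treatment.  We want the Benjamini-Hochberg procedure at FDR 10% to catch
80% of the responders.  The four conventions for the operational pi0 give
slightly different common p-value cutoffs.
"""

from fdrpower import DesignGoal, solve_alpha

for method in ("BH", "HM", "HH", "JUNG"):
    goal = DesignGoal(fdr=0.1, avg_power=0.8, pi0=0.99, method=method)
    sol = solve_alpha(goal)
    print(f"{method:>4}: alpha = {sol.alpha:.7g}   (operational pi0 at alpha: {sol.pi0_tilde:.5f})")

# The ordering BH <= HM <= HH <= Jung always holds: procedures that use a
# larger operational pi0 in the FDR numerator need a smaller cutoff to hit
# the same target FDR.  Each alpha is then handed to a per-test power
# formula to find the sample size (see the other examples).
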