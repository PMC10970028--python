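# Methods

## The FDR / average-power relation

All calculations start from the approximation

τ̃(α) = π̃₀ α / ( π₀ α + (1 − π₀)(1 − β) ),

valid when the number of tests m is large and test statistics are
(approximately) independent: the numerator is the expected fraction of
null p-values below α scaled by the operational π̃₀, the denominator the
average p-value CDF across all tests.  The package treats π₀ strictly
inside (0, 1): with π₀ = 1 average power is undefined (no false nulls)
and with π₀ = 0 the FDR is identically 0, so both endpoints raise.

The four π̃₀ conventions (`JUNG`, `BH`, `HH`, `HM`) are solved in closed
form; HH and HM reduce to quadratics in α:

- HH: π₀(τ−1)α² + [π₀(1−τ) + (1−π₀)β + τ(1−π₀)(1−β)]α − τ(1−π₀)(1−β) = 0
- HM: (1−π₀)α² + [π₀(1−τ) + (1−π₀)β]α − τ(1−π₀)(1−β) = 0

Numerics: the quadratics are solved with the cancellation-safe form
q = −(B + sign(B)√(B²−4AC))/2, roots q/A and C/q, because the constant
term τ(1−π₀)(1−β) can be many orders smaller than B.  When both roots lie
in (0, 1) the smaller is returned: τ̃(α) is the modeled FDR at threshold
α, and the operational threshold is the least α reaching the target.  The
HM quadratic provably has exactly one positive root (A > 0, C < 0).  Two
facts worth recording:

- The BH solution is always feasible: α_BH < 1 ⇔ τ(π₀ + (1−π₀)(1−β)) < 1,
  which holds for every valid goal.  Only the Jung form can exceed 1
  (few nulls plus a lax FDR target), which raises an infeasible-design
  error naming the inputs.
- A solved HM threshold always satisfies α + β < 1 when τ < 1 (at
  α = 1 − β the relation forces τ = 1), so the three-rectangle regime
  cannot be left by solving.  Direct evaluation of the histogram-mean π̃₀
  with α + β > 1 is outside the model and emits a RuntimeWarning, since
  there the usual ordering α_BH ≤ α_HM ≤ α_HH ≤ α_Jung flips.

## Per-test power formulas

Power is the probability of rejection at the fixed two-sided level α,
with z_α = Φ⁻¹(1 − α/2).  Families and sample-size semantics:

| family | formula | n counts |
|---|---|---|
| sign | Dixon–Mood normal approx., null variance in the critical value, alternative variance in the tail | subjects |
| one/two-sample t | noncentral t, df n−1 / 2n−2, ncp δ√n / δ√(n/2), both tails | subjects / per group |
| rank–sum | Noether: Φ(√(6n)\|p′−½\| − z_α), p′ = P(Y > X) | per group |
| signed–rank | Noether: Φ(√(3n)\|p′−½\| − z_α), p′ = P(Xᵢ+Xⱼ > 0) | pairs |
| Fisher exact | full enumeration of 2×2 tables (cap n ≤ 500) | per group |
| correlation | noncentral t, df n−2, ncp ρ√(n−2)/√(1−ρ²) | subjects |
| Poisson pair | exact conditional binomial given the total (tail mass < 1e−12 truncated) | per group |
| negative binomial | Hart: Φ(√(nΔ²/(2(1/μ+σ²))) − z_α) | per group |
| two proportions | pooled-null z approximation | per group |
| one-way ANOVA | noncentral F, df (k−1, k(n−1)), ncp nΣ(μᵢ−μ̄)²/σ² | per group |
| Cox | Hsieh–Lavori: Φ(\|logHR\|√(dv) − z_α) | events d |

Design choices:

- Everything is two-sided; the published threshold and example values
  reproduce only with α/2 quantiles.
- The one-tailed normal approximations report only the tail in the
  effect's direction; at design-scale α the opposite tail is negligible.
  Exact families include both rejection regions, so they return exactly α
  at the null while the approximations return ≈ α/2.
- The correlation ncp uses √(n−2) (plugging ρ into t = r√(n−2)/√(1−r²)).
  The √n variant overshoots simulated power by ~3 percentage points at
  design-scale α (n = 50, ρ = 0.5), well outside Monte-Carlo error.
- Rank tests are parameterized by exceedance probabilities, keeping the
  Noether formulas distribution-free; `normal_shift_to_p_prime` maps a
  normal location shift to p′ for simulation work.  The Noether forms are
  first-order accurate: bias is a few percent at strong effects with small
  n (e.g. p′ = 0.75 at the n they imply) and falls below half a percent at
  moderate effects (p′ ≈ 0.57–0.6 at their implied n).  Tests pin them by
  simulation in the latter regime; the former is exactly the situation the
  simulation harness exists to catch.
- The null predicate is exact equality on the family's parameter (θ = ½,
  δ = 0, Δ = 0, logHR = 0, p₁ = p₂, λ₁ = λ₂, ρ = 0, all means equal); π₀
  is always derived from the effect vector, never passed separately, so a
  goal and a profile cannot silently disagree.
- scipy's noncentral distributions need guarding at the edges: `nct`
  returns NaN at small df with huge ncp (the far tail is replaced by 0 and
  the near tail by its normal limit) and `ncf` is unreliable at zero
  noncentrality (central F is used there).

## Sample-size search

Given the solved α, the search evaluates average power (the mean over
false-null features only) at n₀ = 3 and n₁ = 6, returns n₀ if both already
meet the target, otherwise doubles (n₀ ← n₁, n₁ ← 2n₁) until the target is
bracketed and then bisects (floor midpoints) to the smallest integer n
with average power ≥ 1 − β.  The iteration counter records one
average-power evaluation per doubling round (the old upper bracket is
reused as the new lower) and one per bisection step; the two initial
evaluations are not counted.  A cap (`max_its`, default 50) bounds the
doubling/bisection phase; a capped run reports `converged=False` with the
brackets reached, which can be fed back as (n₀, n₁) to resume.  Power
plateaus below the target therefore terminate rather than loop.  When the
initial n₀ already meets the target the search reports n₀ without probing
below it, so feasible sizes under 3 are only found by passing a smaller
n₀ explicitly.

## Tradeoff table

`fdr_avepow` tabulates (α, FDR, average power) for fixed n with the
operational BH numerator: fdr = α / (π₀α + (1−π₀)·avepow).  The default
grid is 0.001–0.1 in steps of 0.001 (a convention, user-overridable).
Every row satisfies fdr·(π₀α + (1−π₀)avepow) = α to machine precision.

## Monte-Carlo validation harness

`simulate_experiment` draws raw data per feature from the family's data
model, computes actual test p-values, applies the BH step-up at τ, and
averages false-discovery proportion (0 when nothing is rejected — the
standard convention), the fraction of false-null features rejected, and
the realized BH cutoff over replicates.  Data models: Bernoulli outcomes
for the sign test (θ₀ = ½ only; p-values from the exact symmetric binomial
test); normal samples for t/rank/ANOVA families (rank tests use the
location-shift model implied by p′ and continuity-corrected normal-
approximation p-values); bivariate normal for correlation; binomials for
Fisher (p-values from a precomputed exact-table lookup) and the pooled-z
two-proportion test; Poisson totals with the exact conditional binomial
test; negative-binomial counts with variance μ + (σμ)² tested by the
delta-method Wald statistic on the log fold change (the statistic the Hart
formula assumes); exponential survival with a N(0, v) covariate and no
censoring, tested with the Cox score (log-rank-type) test, so every
subject is an event and n means events.  P-values are vectorized across
features; 1,000 replicates over a 200-feature study run in seconds to
tens of seconds per family on one CPU.

What the generator emulates — independent features, correctly specified
data models, equal group sizes — and what it does not: correlation between
features, misspecified distributions, unequal allocation, censoring
patterns.  Passing validation therefore shows the analytic machinery is
self-consistent under ideal conditions, not that a real study with
correlated features will behave identically.  Default replication is
1,000 (with the seed recorded in every report), chosen so the full
seven-family validation stays desk-scale; per-family Monte-Carlo SEs are
~0.003 on power at that size.  The harness deliberately exposes the known
weakness of the asymptotic families: at the tiny thresholds FDR control
requires, the sign, Cox, negative-binomial and two-proportion
approximations can miss their targets (e.g. a Cox design at ~25 events
delivers ~0.53 realized power against an analytic 0.80, and the
small-sample negative-binomial Wald test inflates the realized FDR).
Those discrepancies are recorded — one is asserted as a canary — rather
than patched, and real designs in those families should budget a
simulation check at the chosen n.

## Test-scale choices

Unit tests pin each formula against the exact published numbers where
they exist (threshold grid to 6 decimals, example designs to 7
significant digits) and against seeded Monte-Carlo oracles (10,000
replicates, 3 SE) elsewhere.  Property tests cover threshold ordering and
round-trip identities (1e−10), closed-form vs. bracketed-root agreement
(1e−9, 1,000 random goals), and search minimality vs. exhaustive scan
(100 random designs).  The end-to-end simulation checks run 1,000
replicates per family over 200-feature studies with π₀ between 0.90 and
0.95 — large enough for the large-m FDR approximation to hold, small
enough to complete in about a minute.
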