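"""Smallest sample size achieving target average power at the FDR threshold.

The search solves the fixed p-value threshold ``alpha`` for the design goal
(see :mod:`fdrpower.thresholds`), then finds the smallest integer sample
size whose average power over the false-null features reaches the target:

1. evaluate average power at two starting sizes ``n0 < n1`` (default 3, 6);
2. if both already exceed the target, report ``n0``;
3. otherwise double (``n0 <- n1``, ``n1 <- 2 n1``) until the target is
   bracketed, then bisect down to the smallest ``n`` with average power at
   or above the target;
4. stop after average power has been evaluated ``max_its`` times in the
   doubling/bisection phase, reporting the brackets achieved so far (a
   non-converged result can be resumed from its ``n0``/``n1``).

``n_its`` counts average-power evaluations in the doubling and bisection
steps only; the two initial evaluations are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .profiles import EffectProfile
from .thresholds import AlphaSolution, DesignGoal, solve_alpha

__all__ = [
    "SampleSizeResult",
    "search_sample_size",
    "find_sample_size",
    "n_fdr_signtest",
    "n_fdr_onesamplettest",
    "n_fdr_ttest",
    "n_fdr_ranksum",
    "n_fdr_signedrank",
    "n_fdr_fisher",
    "n_fdr_corr",
    "n_fdr_poisson",
    "n_fdr_negbin",
    "n_fdr_twoprop",
    "n_fdr_anova",
    "n_fdr_coxph",
]


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the smallest-sample-size search.

    ``n`` is the smallest size with average power >= ``desired_avepow``
    when ``converged`` is True; otherwise it is the upper bracket reached
    when the evaluation budget ran out.  ``n0``/``n1`` are the final
    brackets, ``n_its`` the number of average-power evaluations spent in
    the doubling/bisection phase.
    """

    n: int
    computed_avepow: float
    desired_avepow: float
    alpha: float
    n0: int
    n1: int
    n_its: int
    max_its: int
    converged: bool
    desired_fdr: float | None = None
    input_pi0: float | None = None
    method: str | None = None
    n_unit: str = "subjects"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "computed.avepow": self.computed_avepow,
            "desired.avepow": self.desired_avepow,
            "desired.fdr": self.desired_fdr,
            "input.pi0": self.input_pi0,
            "alpha": self.alpha,
            "n0": self.n0,
            "n1": self.n1,
            "n.its": self.n_its,
            "max.its": self.max_its,
            "converged": self.converged,
            "method": self.method,
            "n.unit": self.n_unit,
        }


def search_sample_size(
    avepow: Callable[[int], float],
    target: float,
    n0: int = 3,
    n1: int = 6,
    max_its: int = 50,
) -> SampleSizeResult:
    """Doubling-then-bisection search on an arbitrary average-power function.

    ``avepow(n)`` must be nondecreasing in ``n`` for the result to be the
    true minimum.  See the module docstring for the algorithm and the
    iteration accounting.
    """
    n0, n1 = int(n0), int(n1)
    if not 0 < n0 < n1:
        raise ValueError(f"need 0 < n0 < n1; got n0={n0}, n1={n1}")
    target = float(target)

    p0 = float(avepow(n0))
    p1 = float(avepow(n1))
    its = 0

    def result(n, pw, converged):
        return SampleSizeResult(
            n=int(n), computed_avepow=float(pw), desired_avepow=target,
            alpha=float("nan"), n0=n0, n1=n1, n_its=its, max_its=max_its,
            converged=converged,
        )

    if p0 >= target and p1 >= target:
        return result(n0, p0, True)

    # doubling until the target is bracketed: power(n0) < target <= power(n1)
    while p1 < target:
        if its >= max_its:
            return result(n1, p1, False)
        n0, p0 = n1, p1
        n1 *= 2
        p1 = float(avepow(n1))
        its += 1

    # bisection down to the smallest n with average power >= target
    while n1 - n0 > 1:
        if its >= max_its:
            return result(n1, p1, False)
        mid = (n0 + n1) // 2
        pm = float(avepow(mid))
        its += 1
        if pm >= target:
            n1, p1 = mid, pm
        else:
            n0, p0 = mid, pm

    return result(n1, p1, True)


def find_sample_size(
    goal: DesignGoal,
    profile: EffectProfile,
    n0: int = 3,
    n1: int = 6,
    max_its: int = 50,
) -> SampleSizeResult:
    """Solve the threshold for ``goal`` and search the smallest sample size.

    ``goal.pi0`` must equal the proportion of null features in ``profile``
    (the proportion is always derived from the effect vector, so the two
    cannot silently disagree).
    """
    pi0 = profile.pi0
    if abs(pi0 - goal.pi0) > 1e-12:
        raise ValueError(
            f"goal.pi0 = {goal.pi0} does not match the profile's null "
            f"fraction {pi0}; build the goal from the profile"
        )
    sol: AlphaSolution = solve_alpha(goal)
    res = search_sample_size(
        lambda n: profile.average_power(n, sol.alpha),
        goal.avg_power, n0=n0, n1=n1, max_its=max_its,
    )
    return SampleSizeResult(
        n=res.n, computed_avepow=res.computed_avepow,
        desired_avepow=goal.avg_power, alpha=sol.alpha,
        n0=res.n0, n1=res.n1, n_its=res.n_its, max_its=res.max_its,
        converged=res.converged, desired_fdr=goal.fdr, input_pi0=pi0,
        method=goal.method, n_unit=profile.n_unit,
    )


def _n_fdr(profile, fdr, pwr, pi0_method, n0, n1, max_its):
    goal = DesignGoal(fdr=fdr, avg_power=pwr, pi0=profile.pi0, method=pi0_method)
    return find_sample_size(goal, profile, n0=n0, n1=n1, max_its=max_its)


def n_fdr_signtest(fdr, pwr, theta, theta0=0.5, pi0_method="BH",
                   n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Sample size for many sign tests; ``theta`` is the per-feature vector
    of success probabilities, null at ``theta0``."""
    return _n_fdr(EffectProfile.sign(theta, theta0), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_onesamplettest(fdr, pwr, delta, pi0_method="BH",
                         n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Sample size (subjects) for many one-sample t-tests."""
    return _n_fdr(EffectProfile.one_sample_t(delta), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_ttest(fdr, pwr, delta, pi0_method="BH",
                n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for many two-sample t-tests with standardized
    differences ``delta``."""
    return _n_fdr(EffectProfile.two_sample_t(delta), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_ranksum(fdr, pwr, p_prime, pi0_method="BH",
                  n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for many rank-sum tests with exceedance
    probabilities ``p_prime``."""
    return _n_fdr(EffectProfile.ranksum(p_prime), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_signedrank(fdr, pwr, p_prime, pi0_method="BH",
                     n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Number of pairs for many signed-rank tests."""
    return _n_fdr(EffectProfile.signedrank(p_prime), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_fisher(fdr, pwr, p1, p2, pi0_method="BH",
                 n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for many Fisher exact tests."""
    return _n_fdr(EffectProfile.fisher(p1, p2), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_corr(fdr, pwr, rho, pi0_method="BH",
               n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Sample size (subjects) for many correlation t-tests."""
    return _n_fdr(EffectProfile.corr(rho), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_poisson(fdr, pwr, lambda1, lambda2, pi0_method="BH",
                  n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for many two-group Poisson comparisons."""
    return _n_fdr(EffectProfile.poisson(lambda1, lambda2), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_negbin(fdr, pwr, log_fc, mu, sigma, pi0_method="BH",
                 n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for RNA-seq negative-binomial comparisons."""
    return _n_fdr(EffectProfile.negbin(log_fc, mu, sigma), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_twoprop(fdr, pwr, p1, p2, pi0_method="BH",
                  n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for many two-proportions z-tests."""
    return _n_fdr(EffectProfile.twoprop(p1, p2), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_anova(fdr, pwr, means, sigma=1.0, pi0_method="BH",
                n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Per-group sample size for many one-way ANOVA F-tests."""
    return _n_fdr(EffectProfile.anova(means, sigma), fdr, pwr, pi0_method, n0, n1, max_its)


def n_fdr_coxph(fdr, pwr, log_hr, v=1.0, pi0_method="BH",
                n0=3, n1=6, max_its=50) -> SampleSizeResult:
    """Number of *events* for many single-predictor Cox regressions."""
    return _n_fdr(EffectProfile.cox(log_hr, v), fdr, pwr, pi0_method, n0, n1, max_its)
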