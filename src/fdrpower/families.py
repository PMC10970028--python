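"""Per-test power formulas at a fixed two-sided p-value level.

Each function returns the probability of rejection at the two-sided
unadjusted level ``alpha``; effect parameters broadcast as numpy arrays so a
whole vector of per-feature effects is evaluated in one call.  Throughout,
``z_alpha = Phi^{-1}(1 - alpha/2)`` is the two-sided normal critical value.

Sample-size semantics differ by family and follow the convention of each
formula's source: ``n`` is per group for the two-group families, subjects
for the one-sample families, pairs for the signed-rank test, and the number
of *events* (not enrolled subjects) for Cox regression.

Normal-approximation families (sign, rank tests, two proportions, negative
binomial, Cox) report only the rejection tail in the direction of the
effect; at design-relevant alpha the opposite tail is negligible.  The
exact families (t, F, Fisher, Poisson) include both rejection regions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "power_sign",
    "power_t_one_sample",
    "power_t_two_sample",
    "power_ranksum",
    "power_signedrank",
    "power_fisher",
    "power_corr",
    "power_poisson",
    "power_negbin",
    "power_twoprop",
    "power_anova",
    "power_cox",
    "normal_shift_to_p_prime",
]

#: Enumeration cap for the exact Fisher power (kept deterministic).
FISHER_MAX_N = 500

#: Poisson total-count tail mass discarded in the exact conditional power.
POISSON_TAIL_MASS = 1e-12


def _z(alpha):
    return stats.norm.isf(np.asarray(alpha, dtype=float) / 2.0)


def power_sign(n, theta, alpha, theta0=0.5):
    """Power of the sign test by the Dixon–Mood normal approximation.

    The number of successes is Binomial(n, theta); the critical value uses
    the null variance ``n theta0 (1 - theta0)`` and the rejection
    probability the alternative variance ``n theta (1 - theta)``:

        Phi( (n |theta - theta0| - z_alpha sqrt(n theta0 (1 - theta0)))
             / sqrt(n theta (1 - theta)) )

    At ``theta = theta0`` this returns the level alpha rather than raising.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0) | (theta >= 1)):
        raise ValueError("theta must lie strictly in (0, 1)")
    n = np.asarray(n, dtype=float)
    num = n * np.abs(theta - theta0) - _z(alpha) * np.sqrt(n * theta0 * (1 - theta0))
    return stats.norm.cdf(num / np.sqrt(n * theta * (1 - theta)))


def power_t_one_sample(n, delta, alpha):
    """Power of the one-sample t-test for a standardized mean ``delta``.

    Exact under normality: noncentral t with ``n - 1`` degrees of freedom
    and noncentrality ``delta * sqrt(n)``; both tails included.
    """
    return _nct_power(np.asarray(n) - 1, np.asarray(delta) * np.sqrt(n), alpha)


def power_t_two_sample(n, delta, alpha):
    """Power of the equal-variance two-sample t-test, ``n`` per group.

    Exact under normality: noncentral t with ``2n - 2`` degrees of freedom
    and noncentrality ``delta * sqrt(n / 2)`` for a standardized mean
    difference ``delta``; both tails included.
    """
    n = np.asarray(n)
    if np.any(n < 2):
        raise ValueError("two-sample t-test needs n >= 2 per group")
    return _nct_power(2 * n - 2, np.asarray(delta) * np.sqrt(n / 2.0), alpha)


def _nct_power(df, ncp, alpha):
    # symmetric in the sign of the noncentrality, so fold to ncp >= 0
    ncp = np.abs(np.asarray(ncp, dtype=float))
    tcrit = stats.t.isf(np.asarray(alpha, dtype=float) / 2.0, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # scipy's nct loses precision at small df with huge ncp: the far tail is
    # astronomically small and the near tail is ~ the normal limit
    lower = np.where(np.isnan(lower), 0.0, lower)
    upper = np.where(np.isnan(upper), stats.norm.cdf(ncp - tcrit), upper)
    return np.clip(upper + lower, 0.0, 1.0)


def power_ranksum(n, p_prime, alpha):
    """Noether approximation to Wilcoxon rank-sum power, ``n`` per group.

    Parameterized by the exceedance probability ``p' = P(Y > X)`` (1/2 under
    the null), which keeps the formula distribution-free:

        Phi( sqrt(6 n) |p' - 1/2| - z_alpha )

    (i.e. sqrt(12 c (1 - c) N) with N = 2n total and allocation c = 1/2).
    """
    p_prime = np.asarray(p_prime, dtype=float)
    return stats.norm.cdf(np.sqrt(6.0 * np.asarray(n)) * np.abs(p_prime - 0.5) - _z(alpha))


def power_signedrank(n, p_prime, alpha):
    """Noether approximation to Wilcoxon signed-rank power for ``n`` pairs.

    Parameterized by ``p' = P(X_i + X_j > 0)`` for independent within-sample
    pairs (1/2 under a symmetric-about-zero null):

        Phi( sqrt(3 n) |p' - 1/2| - z_alpha )
    """
    p_prime = np.asarray(p_prime, dtype=float)
    return stats.norm.cdf(np.sqrt(3.0 * np.asarray(n)) * np.abs(p_prime - 0.5) - _z(alpha))


def normal_shift_to_p_prime(shift, kind="ranksum"):
    """Map a normal location shift to the exceedance probability p'.

    For X ~ N(0, 1) and Y ~ N(shift, 1): P(Y > X) = Phi(shift / sqrt(2)).
    For the signed-rank test on X_i ~ N(shift, 1):
    P(X_i + X_j > 0) = Phi(shift * sqrt(2)).
    """
    shift = np.asarray(shift, dtype=float)
    if kind == "ranksum":
        return stats.norm.cdf(shift / np.sqrt(2.0))
    if kind == "signedrank":
        return stats.norm.cdf(shift * np.sqrt(2.0))
    raise ValueError(f"unknown kind {kind!r}")


@lru_cache(maxsize=64)
def _fisher_pvalue_table(n: int) -> np.ndarray:
    """Two-sided Fisher exact p-values for every 2x2 table with margins n, n.

    Entry [x1, x2] is the p-value for x1 successes of n in group 1 and x2 of
    n in group 2: conditioning on the success margin s = x1 + x2, the sum of
    hypergeometric probabilities no larger than that of the observed table
    (with a small relative tolerance against floating-point ties).
    """
    pv = np.ones((n + 1, n + 1))
    for s in range(0, 2 * n + 1):
        lo, hi = max(0, s - n), min(n, s)
        k = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(k, 2 * n, s, n)
        for x1, p_obs in zip(k, pmf):
            pv[x1, s - x1] = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    return np.minimum(pv, 1.0)


def power_fisher(n, p1, p2, alpha):
    """Exact power of the two-sided Fisher exact test, ``n`` per group.

    Enumerates all (x1, x2) outcomes: sums Binomial(n, p1) x Binomial(n, p2)
    probability over the tables whose Fisher p-value is <= alpha.  The
    enumeration is capped at n = 500 per group to bound runtime.
    """
    n = int(n)
    if n > FISHER_MAX_N:
        raise ValueError(
            f"Fisher power enumeration capped at n = {FISHER_MAX_N} per group; got {n}"
        )
    reject = _fisher_pvalue_table(n) <= float(alpha)
    x = np.arange(n + 1)
    scalar = np.ndim(p1) == 0 and np.ndim(p2) == 0
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    p1, p2 = np.broadcast_arrays(p1, p2)
    out = np.empty(p1.shape)
    for i in np.ndindex(out.shape):
        w = np.outer(stats.binom.pmf(x, n, p1[i]), stats.binom.pmf(x, n, p2[i]))
        out[i] = w[reject].sum()
    return float(out[0]) if scalar else out


def power_corr(n, rho, alpha):
    """Power of the t-test for a non-zero Pearson correlation.

    Noncentral-t approximation with ``n - 2`` degrees of freedom and
    noncentrality ``rho sqrt(n) / sqrt(1 - rho^2)``; symmetric in the sign
    of rho.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("rho must lie in (-1, 1)")
    # plug rho into t = r sqrt(n-2)/sqrt(1-r^2); the sqrt(n) variant
    # overshoots simulated power noticeably at design-scale alpha
    ncp = rho * np.sqrt(np.asarray(n) - 2) / np.sqrt(1.0 - rho**2)
    return _nct_power(np.asarray(n) - 2, ncp, alpha)


def _binom_halves_pvalue(x, t):
    """Two-sided exact binomial p-value for proportion 1/2, vectorized."""
    k = np.minimum(x, t - x)
    return np.minimum(1.0, stats.binom.cdf(k, t, 0.5) + stats.binom.sf(t - k - 1, t, 0.5))


def power_poisson(n, lambda1, lambda2, alpha):
    """Exact power of the conditional test comparing two Poisson rates.

    With per-group totals X_g summing n counts of rate lambda_g, the total
    T = X1 + X2 is Poisson(n (lambda1 + lambda2)) and X1 | T is
    Binomial(T, lambda1 / (lambda1 + lambda2)).  Power is the T-average of
    the exact binomial test of proportion 1/2 at level alpha, truncating T
    where the Poisson tail mass drops below 1e-12.
    """
    scalar = np.ndim(lambda1) == 0 and np.ndim(lambda2) == 0
    lambda1 = np.atleast_1d(np.asarray(lambda1, dtype=float))
    lambda2 = np.atleast_1d(np.asarray(lambda2, dtype=float))
    lambda1, lambda2 = np.broadcast_arrays(lambda1, lambda2)
    out = np.empty(lambda1.shape)
    alpha = float(alpha)
    for i in np.ndindex(out.shape):
        mu = float(n) * (lambda1[i] + lambda2[i])
        theta = lambda1[i] / (lambda1[i] + lambda2[i])
        t_lo = int(stats.poisson.ppf(POISSON_TAIL_MASS, mu))
        t_hi = int(stats.poisson.isf(POISSON_TAIL_MASS, mu))
        acc = 0.0
        for t in range(max(t_lo, 1), t_hi + 1):
            k = np.arange(0, t // 2 + 1)
            pv = _binom_halves_pvalue(k, t)
            sig = np.nonzero(pv <= alpha)[0]
            if sig.size == 0:
                continue
            k_lo = sig[-1]  # reject when X1 <= k_lo or X1 >= t - k_lo
            rej = stats.binom.cdf(k_lo, t, theta) + stats.binom.sf(t - k_lo - 1, t, theta)
            acc += stats.poisson.pmf(t, mu) * rej
        out[i] = acc
    return float(out[0]) if scalar else out


def power_negbin(n, log_fc, mu, sigma, alpha):
    """RNA-seq differential-expression power for negative binomial counts.

    Hart-style Wald approximation for a two-group comparison with ``n``
    subjects per group, natural-log fold change ``log_fc``, mean read depth
    ``mu`` per gene, and per-gene coefficient of variation ``sigma``:

        Phi( sqrt( n log_fc^2 / (2 (1/mu + sigma^2)) ) - z_alpha )
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mean read depth mu must be positive")
    if np.any(sigma < 0):
        raise ValueError("coefficient of variation sigma must be non-negative")
    lfc = np.asarray(log_fc, dtype=float)
    ncp = np.sqrt(np.asarray(n) * lfc**2 / (2.0 * (1.0 / mu + sigma**2)))
    return stats.norm.cdf(ncp - _z(alpha))


def power_twoprop(n, p1, p2, alpha):
    """Pooled-null normal approximation for the two-proportions z-test.

    With pooled proportion ``pbar = (p1 + p2) / 2``:

        Phi( (|p1 - p2| - z_alpha sqrt(2 pbar (1 - pbar) / n))
             / sqrt(p1 (1 - p1)/n + p2 (1 - p2)/n) )
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)):
        raise ValueError("proportions must lie strictly in (0, 1)")
    n = np.asarray(n, dtype=float)
    pbar = (p1 + p2) / 2.0
    num = np.abs(p1 - p2) - _z(alpha) * np.sqrt(2.0 * pbar * (1 - pbar) / n)
    den = np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
    return stats.norm.cdf(num / den)


def power_anova(n, group_means, sigma, alpha):
    """Exact power of the one-way ANOVA F-test with ``n`` per group.

    ``group_means`` holds the k group means of one feature (1-D) or one row
    per feature (2-D); ``sigma`` is the common within-group SD.  Noncentral
    F with (k - 1, k (n - 1)) degrees of freedom and noncentrality
    ``n * sum_i (mu_i - mubar)^2 / sigma^2``.  Invariant to adding a
    constant to all means.
    """
    means = np.atleast_2d(np.asarray(group_means, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("within-group sigma must be positive")
    k = means.shape[1]
    ncp = np.asarray(n) * ((means - means.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / sigma**2
    df1, df2 = k - 1, k * (np.asarray(n) - 1)
    fcrit = stats.f.isf(float(alpha), df1, df2)
    # scipy's noncentral F is unreliable at nc == 0; fall back to central F
    out = np.where(
        ncp > 0,
        stats.ncf.sf(fcrit, df1, df2, np.maximum(ncp, 1e-300)),
        stats.f.sf(fcrit, df1, df2),
    )
    return out if np.ndim(group_means) > 1 else float(out[0])


def power_cox(n_events, log_hr, v, alpha):
    """Hsieh–Lavori power for single-predictor Cox regression.

    ``n_events`` is the number of observed events d (progressions/deaths),
    ``log_hr`` the log hazard ratio per unit of the covariate, and ``v``
    the covariate variance:

        Phi( |log_hr| sqrt(d v) - z_alpha )
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("covariate variance v must be positive")
    d = np.asarray(n_events, dtype=float)
    if np.any(d < 1):
        raise ValueError("number of events must be >= 1")
    return stats.norm.cdf(np.abs(np.asarray(log_hr, dtype=float)) * np.sqrt(d * v) - _z(alpha))
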