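"""Per-family power formulas: published values, null behavior, monotonicity,
and Monte-Carlo oracles for the families without printed reference numbers."""

import numpy as np
import pytest
from scipy import stats

from fdrpower import families as fam

ALPHA_BH = 0.0008879023307436191  # BH threshold for tau=0.1, power=0.8, pi0=0.99


# -- published reference values ---------------------------------------------


def test_sign_test_reference_values():
    """Dixon-Mood power at the designed threshold matches the published 0.8095842."""
    assert fam.power_sign(45, 0.8, ALPHA_BH) == pytest.approx(0.8095842, abs=1e-7)
    assert fam.power_sign(44, 0.8, ALPHA_BH) < 0.8


def test_cox_reference_values():
    """Hsieh-Lavori power at 37 events matches the published 0.8139159."""
    assert fam.power_cox(37, np.log(2), 1.0, ALPHA_BH) == pytest.approx(0.8139159, abs=1e-7)
    assert fam.power_cox(36, np.log(2), 1.0, ALPHA_BH) < 0.8


def test_negbin_reference_values():
    """Hart RNA-seq power at n=20 matches the published 0.8087842."""
    assert fam.power_negbin(20, np.log(2.7), 5.0, 0.6, ALPHA_BH) == pytest.approx(
        0.8087842, abs=1e-7
    )
    assert fam.power_negbin(19, np.log(2.7), 5.0, 0.6, ALPHA_BH) < 0.8


def test_two_sample_t_reference_values():
    """Noncentral-t power reproduces the published tradeoff-table entries."""
    assert fam.power_t_two_sample(10, 2.0, 0.001) == pytest.approx(0.6951602, abs=1e-7)
    assert fam.power_t_two_sample(10, 2.0, 0.005) == pytest.approx(0.8780755, abs=1e-7)


# -- behavior at the null ----------------------------------------------------


@pytest.mark.parametrize("alpha", [0.005, 0.05])
@pytest.mark.parametrize(
    "power_at_null,exact",
    [
        (lambda a: fam.power_t_two_sample(15, 0.0, a), True),
        (lambda a: fam.power_t_one_sample(15, 0.0, a), True),
        (lambda a: fam.power_corr(30, 0.0, a), True),
        (lambda a: fam.power_anova(12, [1.0, 1.0, 1.0], 1.0, a), True),
        (lambda a: fam.power_sign(40, 0.5, a), False),       # level-alpha tail
        (lambda a: fam.power_cox(40, 0.0, 1.0, a), False),   # one-tailed approx: alpha/2
        (lambda a: fam.power_negbin(20, 0.0, 5.0, 0.6, a), False),
        (lambda a: fam.power_ranksum(30, 0.5, a), False),
        (lambda a: fam.power_signedrank(30, 0.5, a), False),
    ],
)
def test_power_at_null_is_level(power_at_null, exact, alpha):
    """Exact families give exactly alpha at the null; one-tailed normal
    approximations give the single-tail alpha/2."""
    value = float(np.asarray(power_at_null(alpha)))
    if exact:
        assert value == pytest.approx(alpha, rel=1e-9)
    else:
        assert value <= alpha + 1e-12
        assert value >= alpha / 4


def test_exact_discrete_families_are_valid_at_null():
    """Fisher and conditional-Poisson tests never exceed the nominal level."""
    assert fam.power_fisher(20, 0.3, 0.3, 0.05) <= 0.05
    assert fam.power_poisson(10, 2.0, 2.0, 0.05) <= 0.05


# -- monotonicity ------------------------------------------------------------


@pytest.mark.parametrize(
    "power_of_n",
    [
        lambda n: fam.power_sign(n, 0.7, 0.01),
        lambda n: fam.power_t_two_sample(n, 0.8, 0.01),
        lambda n: fam.power_t_one_sample(n, 0.5, 0.01),
        lambda n: fam.power_ranksum(n, 0.65, 0.01),
        lambda n: fam.power_signedrank(n, 0.65, 0.01),
        lambda n: fam.power_fisher(n, 0.2, 0.6, 0.01),
        lambda n: fam.power_corr(n, 0.4, 0.01),
        lambda n: fam.power_poisson(n, 2.0, 4.0, 0.01),
        lambda n: fam.power_negbin(n, 0.7, 5.0, 0.6, 0.01),
        lambda n: fam.power_twoprop(n, 0.3, 0.5, 0.01),
        lambda n: fam.power_anova(n, [0.0, 0.5, 1.0], 1.0, 0.01),
        lambda n: fam.power_cox(n, 0.5, 1.0, 0.01),
    ],
    ids=[
        "sign", "two_t", "one_t", "ranksum", "signedrank", "fisher",
        "corr", "poisson", "negbin", "twoprop", "anova", "cox",
    ],
)
def test_power_nondecreasing_in_n(power_of_n):
    sizes = [5, 10, 20, 40, 80]
    values = [float(np.asarray(power_of_n(n))) for n in sizes]
    assert np.all(np.diff(values) >= -1e-12)
    assert values[-1] > values[0]


def test_power_increasing_in_alpha():
    alphas = [1e-4, 1e-3, 1e-2, 0.05]
    for f in (
        lambda a: fam.power_sign(30, 0.7, a),
        lambda a: fam.power_t_two_sample(12, 0.8, a),
        lambda a: fam.power_cox(30, 0.5, 1.0, a),
        lambda a: fam.power_poisson(10, 2.0, 4.0, a),
    ):
        values = [float(np.asarray(f(a))) for a in alphas]
        assert np.all(np.diff(values) > -1e-12)


def test_symmetries():
    assert fam.power_corr(40, 0.4, 0.01) == pytest.approx(fam.power_corr(40, -0.4, 0.01))
    assert fam.power_t_two_sample(12, 1.0, 0.01) == pytest.approx(
        fam.power_t_two_sample(12, -1.0, 0.01)
    )
    # ANOVA power is invariant to a common shift of all group means
    assert fam.power_anova(15, [0.0, 0.3, 0.9], 1.0, 0.01) == pytest.approx(
        fam.power_anova(15, [5.0, 5.3, 5.9], 1.0, 0.01), rel=1e-12
    )


def test_fisher_enumeration_cap():
    with pytest.raises(ValueError, match="capped"):
        fam.power_fisher(501, 0.2, 0.4, 0.01)


def test_shift_to_p_prime_mapping():
    assert fam.normal_shift_to_p_prime(0.0) == pytest.approx(0.5)
    assert fam.normal_shift_to_p_prime(1.0, "ranksum") == pytest.approx(
        stats.norm.cdf(1 / np.sqrt(2))
    )
    assert fam.normal_shift_to_p_prime(1.0, "signedrank") == pytest.approx(
        stats.norm.cdf(np.sqrt(2))
    )


# -- Monte-Carlo oracles for families without printed values -----------------

REPS = 10000


def _mc_se(p):
    return np.sqrt(max(p * (1 - p), 1e-12) / REPS)


def test_one_sample_t_matches_simulation():
    rng = np.random.default_rng(101)
    x = rng.normal(0.8, 1.0, size=(REPS, 20))
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(20))
    sim = float((2 * stats.t.sf(np.abs(t), 19) <= 0.01).mean())
    assert fam.power_t_one_sample(20, 0.8, 0.01) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_ranksum_matches_simulation_under_location_shift():
    """Noether power vs simulated Wilcoxon rank-sum at a moderate shift."""
    n, p_prime, alpha = 50, 0.6, 0.01
    shift = np.sqrt(2) * stats.norm.ppf(p_prime)
    rng = np.random.default_rng(102)
    x = rng.normal(0.0, 1.0, (REPS, n))
    y = rng.normal(shift, 1.0, (REPS, n))
    ranks = stats.rankdata(np.concatenate([x, y], axis=1), axis=1)
    r1 = ranks[:, :n].sum(axis=1)
    mean, sd = n * (2 * n + 1) / 2, np.sqrt(n * n * (2 * n + 1) / 12)
    sim = float((2 * stats.norm.sf((np.abs(r1 - mean) - 0.5) / sd) <= alpha).mean())
    assert fam.power_ranksum(n, p_prime, alpha) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_signedrank_matches_simulation():
    n, p_prime, alpha = 400, 0.6, 0.01
    mu = stats.norm.ppf(p_prime) / np.sqrt(2)
    rng = np.random.default_rng(103)
    x = rng.normal(mu, 1.0, (REPS, n))
    ranks = stats.rankdata(np.abs(x), axis=1)
    w = np.where(x > 0, ranks, 0.0).sum(axis=1)
    mean, sd = n * (n + 1) / 4, np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    sim = float((2 * stats.norm.sf((np.abs(w - mean) - 0.5) / sd) <= alpha).mean())
    assert fam.power_signedrank(n, p_prime, alpha) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_corr_matches_simulation():
    n, rho, alpha = 50, 0.5, 0.001
    rng = np.random.default_rng(104)
    z1 = rng.normal(size=(REPS, n))
    y = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=(REPS, n))
    z1c = z1 - z1.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (z1c * yc).sum(axis=1) / np.sqrt((z1c**2).sum(axis=1) * (yc**2).sum(axis=1))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    sim = float((2 * stats.t.sf(np.abs(t), n - 2) <= alpha).mean())
    assert fam.power_corr(n, rho, alpha) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_poisson_matches_simulation():
    n, l1, l2, alpha = 10, 3.0, 1.0, 0.005
    rng = np.random.default_rng(105)
    x1 = rng.poisson(n * l1, REPS)
    t = x1 + rng.poisson(n * l2, REPS)
    k = np.minimum(x1, t - x1)
    p = np.minimum(1, stats.binom.cdf(k, t, 0.5) + stats.binom.sf(t - k - 1, t, 0.5))
    sim = float((p <= alpha).mean())
    assert fam.power_poisson(n, l1, l2, alpha) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_fisher_matches_simulation():
    from fdrpower.families import _fisher_pvalue_table

    n, p1, p2, alpha = 20, 0.9, 0.1, 0.01
    rng = np.random.default_rng(106)
    table = _fisher_pvalue_table(n)
    sim = float((table[rng.binomial(n, p1, REPS), rng.binomial(n, p2, REPS)] <= alpha).mean())
    assert fam.power_fisher(n, p1, p2, alpha) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_anova_matches_simulation():
    n, means, alpha = 15, np.array([0.0, 0.0, 0.8]), 0.01
    rng = np.random.default_rng(107)
    x = rng.normal(means[None, :, None], 1.0, size=(REPS, 3, n))
    gm = x.mean(axis=2)
    ssb = n * ((gm - gm.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssw = ((x - gm[:, :, None]) ** 2).sum(axis=(1, 2))
    f = (ssb / 2) / (ssw / (3 * (n - 1)))
    sim = float((stats.f.sf(f, 2, 3 * (n - 1)) <= alpha).mean())
    assert fam.power_anova(n, means, 1.0, alpha) == pytest.approx(sim, abs=3 * _mc_se(sim))


def test_twoprop_close_to_simulation():
    """The pooled-z approximation tracks simulation at a moderate level; it is
    known to drift at very small alpha, so the tolerance is loose."""
    n, p1, p2, alpha = 80, 0.5, 0.3, 0.01
    rng = np.random.default_rng(108)
    x1 = rng.binomial(n, p1, REPS) / n
    x2 = rng.binomial(n, p2, REPS) / n
    pbar = (x1 + x2) / 2
    z = (x1 - x2) / np.sqrt(pbar * (1 - pbar) * 2 / n)
    sim = float((2 * stats.norm.sf(np.abs(z)) <= alpha).mean())
    assert fam.power_twoprop(n, p1, p2, alpha) == pytest.approx(sim, abs=0.03)
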