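"""Per-feature effect profiles and average power across a study.

An :class:`EffectProfile` bundles a test family with the per-feature effect
parameters of every feature in the planned study (e.g. 10,000 genes).  The
family's null predicate splits features into true nulls and false nulls;
the proportion of true nulls is the study's pi0, and *average power* is the
mean rejection probability over exactly the false-null features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import families

__all__ = ["FAMILIES", "EffectProfile"]


def _vec(x, m=None):
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if m is not None and a.size == 1:
        a = np.full(m, a[0])
    return a


class _Family:
    def __init__(self, name, params, null_mask, power, n_unit):
        self.name = name
        self.params = params          # ordered parameter names
        self.null_mask = null_mask    # params dict -> boolean array (True = true null)
        self.power = power            # (n, alpha, params) -> per-feature power
        self.n_unit = n_unit          # documentation of what n counts


FAMILIES: dict[str, _Family] = {}


def _register(name, params, null_mask, power, n_unit):
    FAMILIES[name] = _Family(name, params, null_mask, power, n_unit)


_register(
    "sign", ("theta", "theta0"),
    lambda p: p["theta"] == p["theta0"],
    lambda n, a, p: families.power_sign(n, p["theta"], a, theta0=p["theta0"]),
    "subjects",
)
_register(
    "one_sample_t", ("delta",),
    lambda p: p["delta"] == 0.0,
    lambda n, a, p: families.power_t_one_sample(n, p["delta"], a),
    "subjects",
)
_register(
    "two_sample_t", ("delta",),
    lambda p: p["delta"] == 0.0,
    lambda n, a, p: families.power_t_two_sample(n, p["delta"], a),
    "subjects per group",
)
_register(
    "ranksum", ("p_prime",),
    lambda p: p["p_prime"] == 0.5,
    lambda n, a, p: families.power_ranksum(n, p["p_prime"], a),
    "subjects per group",
)
_register(
    "signedrank", ("p_prime",),
    lambda p: p["p_prime"] == 0.5,
    lambda n, a, p: families.power_signedrank(n, p["p_prime"], a),
    "pairs",
)
_register(
    "fisher", ("p1", "p2"),
    lambda p: p["p1"] == p["p2"],
    lambda n, a, p: families.power_fisher(n, p["p1"], p["p2"], a),
    "subjects per group",
)
_register(
    "corr", ("rho",),
    lambda p: p["rho"] == 0.0,
    lambda n, a, p: families.power_corr(n, p["rho"], a),
    "subjects",
)
_register(
    "poisson", ("lambda1", "lambda2"),
    lambda p: p["lambda1"] == p["lambda2"],
    lambda n, a, p: families.power_poisson(n, p["lambda1"], p["lambda2"], a),
    "subjects per group",
)
_register(
    "negbin", ("log_fc", "mu", "sigma"),
    lambda p: p["log_fc"] == 0.0,
    lambda n, a, p: families.power_negbin(n, p["log_fc"], p["mu"], p["sigma"], a),
    "subjects per group",
)
_register(
    "twoprop", ("p1", "p2"),
    lambda p: p["p1"] == p["p2"],
    lambda n, a, p: families.power_twoprop(n, p["p1"], p["p2"], a),
    "subjects per group",
)
_register(
    "anova", ("means", "sigma"),
    lambda p: np.ptp(p["means"], axis=1) == 0.0,
    lambda n, a, p: families.power_anova(n, p["means"], p["sigma"], a),
    "subjects per group",
)
_register(
    "cox", ("log_hr", "v"),
    lambda p: p["log_hr"] == 0.0,
    lambda n, a, p: families.power_cox(n, p["log_hr"], p["v"], a),
    "events",
)


@dataclass(frozen=True)
class EffectProfile:
    """A test family plus the per-feature effect parameters of a study.

    Construct with the family-specific classmethods (:meth:`sign`,
    :meth:`two_sample_t`, :meth:`cox`, ...) rather than directly; they
    validate and broadcast the parameter vectors.
    """

    family: str
    params: dict = field(repr=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown test family {self.family!r}; expected one of {sorted(FAMILIES)}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def sign(cls, theta, theta0=0.5) -> "EffectProfile":
        """Sign tests of success probabilities ``theta`` against ``theta0``."""
        theta = _vec(theta)
        if np.any((theta <= 0) | (theta >= 1)):
            raise ValueError("theta must lie strictly in (0, 1)")
        return cls("sign", {"theta": theta, "theta0": _vec(theta0, theta.size)})

    @classmethod
    def one_sample_t(cls, delta) -> "EffectProfile":
        """One-sample t-tests of standardized means ``delta`` against 0."""
        return cls("one_sample_t", {"delta": _vec(delta)})

    @classmethod
    def two_sample_t(cls, delta) -> "EffectProfile":
        """Two-sample t-tests of standardized mean differences ``delta``."""
        return cls("two_sample_t", {"delta": _vec(delta)})

    @classmethod
    def ranksum(cls, p_prime) -> "EffectProfile":
        """Rank-sum tests with exceedance probabilities ``p' = P(Y > X)``."""
        p_prime = _vec(p_prime)
        if np.any((p_prime <= 0) | (p_prime >= 1)):
            raise ValueError("p_prime must lie strictly in (0, 1)")
        return cls("ranksum", {"p_prime": p_prime})

    @classmethod
    def signedrank(cls, p_prime) -> "EffectProfile":
        """Signed-rank tests with ``p' = P(X_i + X_j > 0)``."""
        p_prime = _vec(p_prime)
        if np.any((p_prime <= 0) | (p_prime >= 1)):
            raise ValueError("p_prime must lie strictly in (0, 1)")
        return cls("signedrank", {"p_prime": p_prime})

    @classmethod
    def fisher(cls, p1, p2) -> "EffectProfile":
        """Fisher exact tests comparing success probabilities p1 vs p2."""
        p1, p2 = np.broadcast_arrays(_vec(p1), _vec(p2))
        return cls("fisher", {"p1": p1.copy(), "p2": p2.copy()})

    @classmethod
    def corr(cls, rho) -> "EffectProfile":
        """t-tests of Pearson correlations ``rho`` against 0."""
        rho = _vec(rho)
        if np.any(np.abs(rho) >= 1):
            raise ValueError("rho must lie in (-1, 1)")
        return cls("corr", {"rho": rho})

    @classmethod
    def poisson(cls, lambda1, lambda2) -> "EffectProfile":
        """Exact conditional comparisons of Poisson rates lambda1 vs lambda2."""
        l1, l2 = np.broadcast_arrays(_vec(lambda1), _vec(lambda2))
        if np.any(l1 <= 0) or np.any(l2 <= 0):
            raise ValueError("Poisson rates must be positive")
        return cls("poisson", {"lambda1": l1.copy(), "lambda2": l2.copy()})

    @classmethod
    def negbin(cls, log_fc, mu, sigma) -> "EffectProfile":
        """Negative-binomial (RNA-seq) comparisons.

        ``log_fc`` natural-log fold change per gene, ``mu`` mean read depth,
        ``sigma`` per-gene coefficient of variation.
        """
        lfc = _vec(log_fc)
        return cls(
            "negbin",
            {"log_fc": lfc, "mu": _vec(mu, lfc.size), "sigma": _vec(sigma, lfc.size)},
        )

    @classmethod
    def twoprop(cls, p1, p2) -> "EffectProfile":
        """Two-proportions z-tests comparing p1 vs p2."""
        p1, p2 = np.broadcast_arrays(_vec(p1), _vec(p2))
        return cls("twoprop", {"p1": p1.copy(), "p2": p2.copy()})

    @classmethod
    def anova(cls, means, sigma=1.0) -> "EffectProfile":
        """One-way ANOVA; ``means`` is (features x groups), common SD ``sigma``."""
        means = np.atleast_2d(np.asarray(means, dtype=float))
        if means.shape[1] < 2:
            raise ValueError("ANOVA needs at least two groups")
        return cls("anova", {"means": means, "sigma": _vec(sigma, means.shape[0])})

    @classmethod
    def cox(cls, log_hr, v=1.0) -> "EffectProfile":
        """Single-predictor Cox regressions with log hazard ratios ``log_hr``
        and covariate variances ``v``."""
        log_hr = _vec(log_hr)
        v = _vec(v, log_hr.size)
        if np.any(v <= 0):
            raise ValueError("covariate variance v must be positive")
        return cls("cox", {"log_hr": log_hr, "v": v})

    # -- derived quantities -------------------------------------------------

    @property
    def m(self) -> int:
        """Number of features (hypothesis tests)."""
        first = self.params[FAMILIES[self.family].params[0]]
        return int(np.atleast_2d(first).shape[0]) if first.ndim > 1 else int(first.size)

    @property
    def null_mask(self) -> np.ndarray:
        """Boolean vector: True where the feature satisfies the family null."""
        return np.asarray(FAMILIES[self.family].null_mask(self.params))

    @property
    def pi0(self) -> float:
        """Proportion of features with a true null hypothesis."""
        return float(self.null_mask.mean())

    @property
    def n_unit(self) -> str:
        """What the sample size counts for this family."""
        return FAMILIES[self.family].n_unit

    def power(self, n, alpha) -> np.ndarray:
        """Per-feature rejection probability at sample size ``n``, level ``alpha``."""
        return np.asarray(FAMILIES[self.family].power(n, float(alpha), self.params))

    def average_power(self, n, alpha) -> float:
        """Mean power over the false-null features only."""
        mask = ~self.null_mask
        if not mask.any():
            raise ValueError(
                "profile has no false-null features; average power is undefined"
            )
        return float(self.power(n, alpha)[mask].mean())

    def subset(self, mask) -> "EffectProfile":
        """Profile restricted to the features selected by ``mask``."""
        params = {
            k: (v[mask] if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return EffectProfile(self.family, params)
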