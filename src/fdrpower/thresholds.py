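"""Fixed p-value thresholds that deliver a target FDR and average power.

In a study performing a very large number of hypothesis tests, a proportion
``pi0`` of tests have a true null hypothesis.  For a common (unadjusted)
p-value threshold ``alpha`` applied to every test, the false discovery rate
is well approximated by

    fdr(alpha) = pi0_tilde * alpha / (pi0 * alpha + (1 - pi0) * avg_power)

where ``avg_power`` is the average power of the tests with a false null and
``pi0_tilde`` is the operational value of pi0 used by the FDR procedure:

* ``JUNG`` — the true ``pi0`` (an oracle procedure);
* ``BH``   — 1, as used operationally by the Benjamini–Hochberg step-up
  adjustment, which never estimates pi0;
* ``HH``   — the height of the p-value histogram near p = 1 under a
  three-rectangle approximation of the p-value density,
  ``pi0 + (1 - pi0) * beta / (1 - alpha)``;
* ``HM``   — twice the mean of all p-values under the same approximation,
  ``pi0 + (1 - pi0) * (alpha + beta)``.

Setting the FDR expression equal to the target ``tau`` and solving for
``alpha`` gives a closed form for JUNG and BH and a quadratic for HH and HM.
The solved ``alpha`` is then handed to a per-test power formula to find the
sample size (see :mod:`fdrpower.design`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "METHODS",
    "DesignGoal",
    "AlphaSolution",
    "InfeasibleDesignError",
    "pi0_tilde_hh",
    "pi0_tilde_hm",
    "fdr_at_alpha",
    "solve_alpha_jung",
    "solve_alpha_bh",
    "solve_alpha_hh",
    "solve_alpha_hm",
    "solve_alpha",
]

#: Supported conventions for the operational pi0.
METHODS = ("BH", "JUNG", "HH", "HM")


class InfeasibleDesignError(ValueError):
    """Raised when no p-value threshold in (0, 1) can meet the design goal."""


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1); got {value!r}")
    return value


@dataclass(frozen=True)
class DesignGoal:
    """Target FDR level, target average power, and pi0 handling.

    Parameters
    ----------
    fdr : float
        Target false discovery rate ``tau``, strictly in (0, 1).
    avg_power : float
        Target average power ``1 - beta`` of the tests with a false null,
        strictly in (0, 1).
    pi0 : float
        Proportion of tests with a true null hypothesis, strictly in (0, 1).
        The endpoints are rejected: with no false nulls average power is
        undefined, and with no true nulls the FDR is identically zero.
    method : str
        One of ``"BH"``, ``"JUNG"``, ``"HH"``, ``"HM"`` (case-insensitive).
    """

    fdr: float
    avg_power: float
    pi0: float
    method: str = "BH"

    def __post_init__(self) -> None:
        _check_prob(self.fdr, "fdr")
        _check_prob(self.avg_power, "avg_power")
        pi0 = float(self.pi0)
        if not 0.0 < pi0 < 1.0:
            raise ValueError(
                "pi0 must lie strictly in (0, 1): pi0 = 1 leaves no false "
                f"nulls to power and pi0 = 0 makes the FDR degenerate; got {pi0!r}"
            )
        method = str(self.method).upper()
        if method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        object.__setattr__(self, "method", method)

    @property
    def beta(self) -> float:
        """Target average type II error rate among false nulls."""
        return 1.0 - self.avg_power


@dataclass(frozen=True)
class AlphaSolution:
    """A solved fixed p-value threshold.

    Attributes
    ----------
    alpha : float
        The common unadjusted p-value threshold in (0, 1).
    method : str
        The pi0 convention that produced it.
    goal : DesignGoal
        Echo of the design goal.
    pi0_tilde : float
        The operational pi0 implied at the solved threshold.
    """

    alpha: float
    method: str
    goal: DesignGoal
    pi0_tilde: float = field(repr=False, default=float("nan"))

    def fdr_at(self, alpha: float | None = None) -> float:
        """FDR implied by the model at ``alpha`` (default: the solved one)."""
        a = self.alpha if alpha is None else alpha
        g = self.goal
        return fdr_at_alpha(a, g.pi0, g.avg_power, method=self.method)


def pi0_tilde_hh(pi0: float, alpha: float, beta: float) -> float:
    """Histogram-height approximation of the operational pi0.

    Under the three-rectangle p-value histogram, the density near p = 1 is
    the uniform null mass plus the type II rectangle of the false nulls:
    ``pi0 + (1 - pi0) * beta / (1 - alpha)``.  Always >= pi0.
    """
    if alpha >= 1.0:
        raise ValueError(f"alpha must be < 1; got {alpha!r}")
    return pi0 + (1.0 - pi0) * beta / (1.0 - alpha)


def pi0_tilde_hm(pi0: float, alpha: float, beta: float) -> float:
    """Histogram-mean (twice the mean p-value) approximation of pi0.

    The three rectangles have means alpha/2 (true positives), (1 + alpha)/2
    (type II errors) and 1/2 (true nulls); doubling the mixture mean gives
    ``pi0 + (1 - pi0) * (alpha + beta)``.

    The three-rectangle model presumes ``alpha + beta <= 1`` (the rejection
    region does not swallow the type II rectangle); outside that regime the
    usual HM <= HH ordering flips, so the evaluation is flagged with a
    RuntimeWarning.  A *solved* HM threshold always satisfies
    ``alpha + beta < 1`` when the target FDR is below 1, so
    :func:`solve_alpha_hm` never triggers it.
    """
    if alpha + beta > 1.0:
        warnings.warn(
            "alpha + beta > 1 is outside the three-rectangle histogram "
            "regime; the histogram-mean pi0 may exceed the histogram-height "
            "value and the usual threshold ordering flips",
            RuntimeWarning,
            stacklevel=2,
        )
    return pi0 + (1.0 - pi0) * (alpha + beta)


_PI0_TILDE = {
    "BH": lambda pi0, alpha, beta: 1.0,
    "JUNG": lambda pi0, alpha, beta: pi0,
    "HH": pi0_tilde_hh,
    "HM": pi0_tilde_hm,
}


def fdr_at_alpha(alpha: float, pi0: float, avg_power: float, method: str = "JUNG") -> float:
    """FDR at threshold ``alpha`` under the chosen pi0 convention."""
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    beta = 1.0 - avg_power
    pi0t = _PI0_TILDE[method](pi0, alpha, beta)
    return pi0t * alpha / (pi0 * alpha + (1.0 - pi0) * avg_power)


def _finish(alpha: float, method: str, goal: DesignGoal) -> AlphaSolution:
    if not 0.0 < alpha < 1.0:
        raise InfeasibleDesignError(
            f"{method} threshold alpha = {alpha:.6g} is not in (0, 1) for "
            f"fdr={goal.fdr}, avg_power={goal.avg_power}, pi0={goal.pi0}; "
            "the design goal cannot be met with a fixed p-value threshold"
        )
    pi0t = _PI0_TILDE[method](goal.pi0, alpha, goal.beta)
    return AlphaSolution(alpha=alpha, method=method, goal=goal, pi0_tilde=pi0t)


def solve_alpha_jung(goal: DesignGoal) -> AlphaSolution:
    """Threshold for an oracle procedure that uses the true pi0.

    ``alpha = tau (1 - pi0)(1 - beta) / (pi0 (1 - tau))``.
    """
    tau, pwr, pi0 = goal.fdr, goal.avg_power, goal.pi0
    alpha = tau * (1.0 - pi0) * pwr / (pi0 * (1.0 - tau))
    return _finish(alpha, "JUNG", goal)


def solve_alpha_bh(goal: DesignGoal) -> AlphaSolution:
    """Threshold implied by the Benjamini–Hochberg step-up procedure.

    BH operationally sets the numerator pi0 to 1, giving
    ``alpha = tau (1 - pi0)(1 - beta) / (1 - tau pi0)``.  This is never
    larger than the oracle (JUNG) threshold.
    """
    tau, pwr, pi0 = goal.fdr, goal.avg_power, goal.pi0
    alpha = tau * (1.0 - pi0) * pwr / (1.0 - tau * pi0)
    return _finish(alpha, "BH", goal)


def _stable_quadratic_roots(a: float, b: float, c: float) -> tuple[float, float]:
    """Real roots of a x^2 + b x + c, via the cancellation-safe form.

    Uses q = -(b + sign(b) sqrt(b^2 - 4ac)) / 2 so that the small root is
    computed as c / q rather than by subtracting nearly equal numbers
    (relevant here because tau (1 - pi0) can be tiny).
    """
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        raise InfeasibleDesignError("threshold quadratic has no real root")
    sq = math.sqrt(disc)
    q = -0.5 * (b + math.copysign(sq, b)) if b != 0.0 else math.sqrt(-a * c)
    return q / a, c / q


def _solve_quadratic_alpha(a: float, b: float, c: float, method: str, goal: DesignGoal) -> AlphaSolution:
    roots = [r for r in _stable_quadratic_roots(a, b, c) if 0.0 < r < 1.0]
    if not roots:
        raise InfeasibleDesignError(
            f"{method} threshold quadratic has no root in (0, 1) for "
            f"fdr={goal.fdr}, avg_power={goal.avg_power}, pi0={goal.pi0}"
        )
    # If both roots are admissible, the smaller is the operational threshold:
    # it is the least alpha at which the modeled FDR reaches tau.
    return _finish(min(roots), method, goal)


def solve_alpha_hh(goal: DesignGoal) -> AlphaSolution:
    """Threshold for procedures estimating pi0 by the histogram height at p = 1.

    Substituting the histogram-height pi0 into the FDR relation and clearing
    the (1 - alpha) denominator yields the quadratic

        pi0 (tau - 1) a^2
        + [pi0 (1 - tau) + (1 - pi0) beta + tau (1 - pi0)(1 - beta)] a
        - tau (1 - pi0)(1 - beta) = 0,

    solved for the root in (0, 1).
    """
    tau, pwr, pi0 = goal.fdr, goal.avg_power, goal.pi0
    beta = goal.beta
    a = pi0 * (tau - 1.0)
    b = pi0 * (1.0 - tau) + (1.0 - pi0) * beta + tau * (1.0 - pi0) * pwr
    c = -tau * (1.0 - pi0) * pwr
    return _solve_quadratic_alpha(a, b, c, "HH", goal)


def solve_alpha_hm(goal: DesignGoal) -> AlphaSolution:
    """Threshold for procedures estimating pi0 by twice the mean p-value.

    Substituting the histogram-mean pi0 into the FDR relation yields

        (1 - pi0) a^2 + [pi0 (1 - tau) + (1 - pi0) beta] a
        - tau (1 - pi0)(1 - beta) = 0,

    which has exactly one positive root.
    """
    tau, pwr, pi0 = goal.fdr, goal.avg_power, goal.pi0
    beta = goal.beta
    a = 1.0 - pi0
    b = pi0 * (1.0 - tau) + (1.0 - pi0) * beta
    c = -tau * (1.0 - pi0) * pwr
    return _solve_quadratic_alpha(a, b, c, "HM", goal)


_SOLVERS = {
    "BH": solve_alpha_bh,
    "JUNG": solve_alpha_jung,
    "HH": solve_alpha_hh,
    "HM": solve_alpha_hm,
}


def solve_alpha(goal: DesignGoal) -> AlphaSolution:
    """Solve for the fixed p-value threshold using ``goal.method``."""
    return _SOLVERS[goal.method](goal)
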