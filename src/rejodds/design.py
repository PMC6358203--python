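"""Pre-experimental rejection odds: power, rejection ratio, threshold solving.

The pre-experimental rejection ratio ``R_pre = (1 - beta_bar) / alpha`` is the
odds that a statistically significant result arises under H1 rather than H0,
at even prior odds; multiplying by the prior odds ``pi1/pi0`` gives the
pre-experimental odds of a correct to an incorrect rejection.  Everything here
is computable before any data are collected, from the anticipated effect size,
the design, and the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import nct, norm
from scipy.stats import t as t_dist

from .priors import PriorSpec

__all__ = [
    "TwoSampleDesign",
    "PriorOdds",
    "DesignReport",
    "compute_power",
    "power_under_prior",
    "rejection_ratio",
    "pre_odds",
    "solve_alpha",
    "required_n",
    "design_report",
]


def _check_prob(name: str, value: float, *, closed_top: bool = False) -> float:
    value = float(value)
    top_ok = value <= 1.0 if closed_top else value < 1.0
    if not (0.0 < value and top_ok):
        hi = "1]" if closed_top else "1)"
        raise ValueError(f"{name} must be in (0, {hi}, got {value!r}")
    return value


@dataclass(frozen=True)
class TwoSampleDesign:
    """A planned two-sample test of a standardized mean difference.

    ``effect`` is the anticipated difference of means in standard-deviation
    units; ``family`` chooses between the normal ("z") and Student ("t")
    reference distributions, the latter with ``n1 + n2 - 2`` degrees of
    freedom.
    """

    effect: float
    n1: int
    n2: int
    alpha: float = 0.05
    sides: int = 1
    family: str = "z"

    def __post_init__(self) -> None:
        _check_prob("alpha", self.alpha)
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")
        if self.family not in ("z", "t"):
            raise ValueError("family must be 'z' or 't'")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 observations per group")

    @property
    def noncentrality(self) -> float:
        return self.effect * np.sqrt(self.n1 * self.n2 / (self.n1 + self.n2))


@dataclass(frozen=True)
class PriorOdds:
    """Prior probabilities of the hypotheses and their odds pi1/pi0."""

    pi0: float
    pi1: float

    def __post_init__(self) -> None:
        # closed top: an extreme hypothesis probability like pi1 = 1e-20
        # leaves the complement indistinguishable from 1 in floating point
        _check_prob("pi0", self.pi0, closed_top=True)
        _check_prob("pi1", self.pi1, closed_top=True)
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-12:
            raise ValueError("pi0 + pi1 must equal 1")

    @property
    def odds(self) -> float:
        return self.pi1 / self.pi0

    @classmethod
    def from_odds(cls, odds: float) -> "PriorOdds":
        if odds <= 0:
            raise ValueError("prior odds must be positive")
        return cls(pi0=1.0 / (1.0 + odds), pi1=odds / (1.0 + odds))

    @classmethod
    def from_pi1(cls, pi1: float) -> "PriorOdds":
        return cls(pi0=1.0 - pi1, pi1=pi1)

    @classmethod
    def even(cls) -> "PriorOdds":
        return cls(pi0=0.5, pi1=0.5)


@dataclass(frozen=True)
class DesignReport:
    alpha: float
    average_power: float
    r_pre: float
    o_pre: float | None = None


def _power_from_noncentrality(delta: float, alpha: float, sides: int,
                              family: str = "z", df: float | None = None) -> float:
    if family == "z":
        if sides == 1:
            return float(norm.sf(norm.isf(alpha) - delta))
        zc = norm.isf(alpha / 2)
        return float(norm.sf(zc - delta) + norm.cdf(-zc - delta))
    if df is None:
        raise ValueError("t family needs degrees of freedom")
    if sides == 1:
        return float(nct.sf(t_dist.isf(alpha, df), df, delta))
    tc = t_dist.isf(alpha / 2, df)
    return float(nct.sf(tc, df, delta) + nct.cdf(-tc, df, delta))


def compute_power(design: TwoSampleDesign) -> float:
    """Probability the test statistic lands in the rejection region under
    the anticipated effect.  Two-sided power sums both tails."""
    return _power_from_noncentrality(
        design.noncentrality, design.alpha, design.sides,
        design.family, design.n1 + design.n2 - 2,
    )


def _pointwise_power(theta, alpha: float, sides: int):
    """Power of the one-observation z-model x ~ Normal(theta, 1)."""
    theta = np.asarray(theta, float)
    if sides == 1:
        return norm.sf(norm.isf(alpha) - theta)
    zc = norm.isf(alpha / 2)
    return norm.sf(zc - theta) + norm.cdf(-zc - theta)


def power_under_prior(prior: PriorSpec, alpha: float, sides: int = 1,
                      theta0: float = 0.0) -> float:
    """Average power ``(1 - beta_bar) = \\int (1 - beta(theta)) pi(theta) dtheta``
    for the one-observation z-model.  Point priors reduce exactly to the
    pointwise power; continuous priors are integrated by adaptive quadrature
    (closed form for an untruncated normal prior)."""
    if alpha != 1.0:
        _check_prob("alpha", alpha)
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if prior.kind == "point":
        return float(_pointwise_power(prior.theta1, alpha, sides))
    if prior.kind == "grid":
        w = np.asarray(prior.weights)
        return float(w @ _pointwise_power(np.asarray(prior.thetas), alpha, sides))
    if prior.kind == "normal" and prior.support_sides == 2:
        # theta + Z ~ Normal(mean, 1 + var): power integrates in closed form
        s = np.sqrt(1.0 + prior.var)
        if sides == 1:
            return float(norm.sf((norm.isf(alpha) - prior.mean) / s))
        zc = norm.isf(alpha / 2)
        return float(norm.sf((zc - prior.mean) / s)
                     + norm.cdf((-zc - prior.mean) / s))
    lo, hi = prior.support(theta0)
    val, _ = quad(
        lambda th: _pointwise_power(th, alpha, sides) * prior.pdf(th, theta0),
        lo, hi, limit=200,
    )
    return float(val)


def rejection_ratio(average_power: float, alpha: float) -> float:
    """R_pre = average power / alpha."""
    _check_prob("alpha", alpha)
    _check_prob("average_power", average_power, closed_top=True)
    return average_power / alpha


def pre_odds(prior_odds: PriorOdds, average_power: float, alpha: float) -> float:
    """O_pre = (pi1/pi0) * (1 - beta_bar) / alpha."""
    return prior_odds.odds * rejection_ratio(average_power, alpha)


def solve_alpha(prior_odds: PriorOdds, average_power: float,
                target_odds: float) -> float:
    """Significance threshold achieving the target pre-experimental odds.

    Inverts ``O_pre = odds * power / alpha``; infeasible targets (alpha >= 1)
    raise.
    """
    _check_prob("average_power", average_power, closed_top=True)
    if target_odds <= 0:
        raise ValueError("target odds must be positive")
    alpha = prior_odds.odds * average_power / target_odds
    if alpha >= 1.0:
        raise ValueError(
            f"target odds {target_odds} unreachable: implied alpha {alpha:.3g} >= 1"
        )
    return alpha


def required_n(effect: float, alpha: float, sides: int, family: str,
               target_power: float) -> int:
    """Per-group sample size (equal groups) reaching the target power.

    Solves the continuous sample-size equation power(n) = target and rounds
    to the nearest integer (minimum 2), the convention behind printed
    sample-size tables; e.g. effect 0.21 at one-sided alpha 0.05 gives
    n = 280.4 -> 280 for 80% power.
    """
    _check_prob("alpha", alpha)
    if not (alpha < target_power < 1.0):
        raise ValueError("target power must lie in (alpha, 1)")
    if effect == 0:
        raise ValueError("power cannot exceed alpha at zero effect")

    def power_at(n: float) -> float:
        delta = abs(effect) * np.sqrt(n / 2.0)
        df = max(2 * n - 2, 1.0)
        return _power_from_noncentrality(delta, alpha, sides, family, df)

    if power_at(2) >= target_power:
        return 2
    hi = 4.0
    while power_at(hi) < target_power:
        hi *= 2
        if hi > 2 ** 26:
            raise ValueError("target power unreachable at this effect size")
    n_star = brentq(lambda n: power_at(n) - target_power, 2, hi, xtol=1e-8)
    return max(2, round(n_star))


def design_report(design: TwoSampleDesign,
                  prior_odds: PriorOdds | None = None) -> DesignReport:
    """Assemble alpha, average power, R_pre and (optionally) O_pre."""
    power = compute_power(design)
    r_pre = rejection_ratio(power, design.alpha)
    o_pre = None if prior_odds is None else prior_odds.odds * r_pre
    return DesignReport(alpha=design.alpha, average_power=power,
                        r_pre=r_pre, o_pre=o_pre)
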