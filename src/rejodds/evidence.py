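"""Post-experimental rejection odds: Bayes factors and the p-value bound.

The post-experimental rejection ratio ``R_post(x) = m(x) / f(x | theta0)`` is
the Bayes factor of H1 to H0 — the marginal likelihood of the observed data
under the alternative's prior divided by its likelihood under the null.  The
module also provides the prior-free bound ``1 / (-e p log p)`` valid for
p <= 1/e, the supremum over all priors ``exp(z^2/2)``, the most favorable
nonincreasing prior, and the intrinsic-prior construction for the normal
location model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from statsmodels.stats.proportion import proportions_ztest

from .priors import PriorSpec

__all__ = [
    "ModelSpec",
    "NORMAL_LOCATION",
    "EvidenceReport",
    "IntrinsicConstruction",
    "p_from_statistic",
    "z_from_counts",
    "marginal_likelihood",
    "bayes_factor",
    "bf_sup_all_priors",
    "bf_best_nonincreasing",
    "bf_bound_from_p",
    "variance_test_lr",
    "intrinsic_prior_normal",
    "post_odds",
    "evidence_report",
]


@dataclass(frozen=True)
class ModelSpec:
    """Sampling model for a single summary observation.

    ``normal_location``: x ~ Normal(theta, 1), null theta = theta0 (default 0).
    ``normal_scale``: x ~ Normal(0, sigma^2), null sigma^2 = 1 versus a simple
    alternative sigma1^2.
    """

    family: str = "normal_location"
    theta0: float = 0.0
    sigma1_sq: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal_location", "normal_scale"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "normal_scale":
            if self.sigma1_sq is None or self.sigma1_sq <= 0 or self.sigma1_sq == 1:
                raise ValueError("normal_scale needs sigma1_sq > 0, != 1")


NORMAL_LOCATION = ModelSpec()


@dataclass(frozen=True)
class EvidenceReport:
    statistic: float
    p_value: float
    marginal: float
    r_post: float
    bound: float | None
    o_post: float | None = None


@dataclass(frozen=True)
class IntrinsicConstruction:
    """Intrinsic prior built from an objective estimation prior.

    For the normal location model with the constant estimation prior and a
    minimal imaginary sample of size q = 1, updating the constant prior with
    one imaginary observation drawn under the null and averaging gives the
    proper prior Normal(theta0, 2) — the convolution of two unit normals.
    """

    estimation_prior: str
    q: int
    prior: PriorSpec


def p_from_statistic(z: float, sides: int = 1) -> float:
    """p-value of a standard-normal statistic; two-sided doubles the tail."""
    if sides == 1:
        return float(norm.sf(z))
    if sides == 2:
        return float(2 * norm.sf(abs(z)))
    raise ValueError("sides must be 1 or 2")


def z_from_counts(events1: int, n1: int, events2: int, n2: int) -> float:
    """Pooled two-proportion z-statistic for (group1 - group2) event rates."""
    for events, n in ((events1, n1), (events2, n2)):
        if n < 1 or not (0 <= events <= n):
            raise ValueError("need 0 <= events <= n and n >= 1")
    pooled = (events1 + events2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate data: pooled event rate is 0 or 1")
    stat, _ = proportions_ztest([events1, events2], [n1, n2])
    return float(stat)


def _require_location(model: ModelSpec) -> None:
    if model.family != "normal_location":
        raise TypeError(
            "prior-based marginal likelihoods require the normal_location model; "
            "use variance_test_lr for the scale test"
        )


def marginal_likelihood(prior: PriorSpec, model: ModelSpec, x):
    """Marginal density m(x) = int f(x | theta) pi(theta) dtheta.

    Closed forms throughout: point priors evaluate the density, the uniform
    prior uses normal-CDF differences, the (possibly truncated) normal prior
    the convolution identity, and grid priors a finite mixture.  Accepts
    scalars or arrays in ``x``.
    """
    _require_location(model)
    x = np.asarray(x, float)
    u = x - model.theta0
    if prior.kind == "point":
        out = norm.pdf(x, loc=prior.theta1)
    elif prior.kind == "uniform_from_null":
        a = prior.a
        if prior.support_sides == 1:
            out = (norm.cdf(u) - norm.cdf(u - a)) / a
        else:
            out = (norm.cdf(u + a) - norm.cdf(u - a)) / (2 * a)
    elif prior.kind == "normal":
        s = np.sqrt(1.0 + prior.var)
        full = norm.pdf(x, prior.mean, s)
        if prior.support_sides == 2:
            out = full
        else:
            # conjugate update: theta | x ~ Normal(m_post, v_post); the
            # one-sided prior rescales by the ratio of right-tail masses.
            v_post = prior.var / (1.0 + prior.var)
            m_post = (prior.mean + prior.var * x) / (1.0 + prior.var)
            num_tail = norm.sf((model.theta0 - m_post) / np.sqrt(v_post))
            den_tail = norm.sf((model.theta0 - prior.mean) / np.sqrt(prior.var))
            out = full * num_tail / den_tail
    elif prior.kind == "grid":
        thetas = np.asarray(prior.thetas)
        w = np.asarray(prior.weights)
        out = norm.pdf(x[..., None] - thetas) @ w
    else:  # pragma: no cover - PriorSpec validates kinds
        raise TypeError(f"unsupported prior kind {prior.kind!r}")
    return float(out) if out.ndim == 0 else out


def bayes_factor(prior: PriorSpec, model: ModelSpec, x):
    """R_post(x) = m(x) / f(x | theta0)."""
    _require_location(model)
    x = np.asarray(x, float)
    out = marginal_likelihood(prior, model, x) / norm.pdf(x - model.theta0)
    return float(out) if np.ndim(out) == 0 else out


def bf_sup_all_priors(z: float) -> float:
    """Supremum of the Bayes factor over all priors on theta > 0.

    Attained by a point mass at the maximum likelihood estimate when z > 0,
    giving exp(z^2/2); for z <= 0 the supremum is approached as the point
    mass moves to the null boundary, giving 1.
    """
    if z <= 0:
        return 1.0
    return float(np.exp(z * z / 2.0))


def bf_best_nonincreasing(z: float) -> tuple[float, float]:
    """Most favorable nonincreasing prior: the best Uniform(0, a).

    Maximizes the Bayes factor over a by bounded scalar search; returns
    (a*, BF).  At z = 2.06 this recovers a* = 2.95, BF = 5.63.
    """
    if z <= 0:
        raise ValueError("best nonincreasing prior needs z > 0")

    def neg(a: float) -> float:
        return -bayes_factor(PriorSpec.uniform_from_null(a), NORMAL_LOCATION, z)

    res = minimize_scalar(neg, bounds=(1e-6, z + 10.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x), float(-res.fun)


_INV_E = 1.0 / np.e


def bf_bound_from_p(p: float) -> float | None:
    """Upper bound 1 / (-e p ln p) on any Bayes factor, valid for p <= 1/e.

    For p > 1/e the bound formula does not apply and ``None`` is returned
    rather than extrapolating outside its validity.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p!r}")
    if p > _INV_E:
        return None
    return float(1.0 / (-np.e * p * np.log(p)))


def variance_test_lr(x: float, sigma1_sq: float) -> float:
    """Likelihood ratio of Normal(0, sigma1^2) to Normal(0, 1) at x.

    The Bayes factor for the simple scale test H0: sigma^2 = 1 versus
    H1: sigma^2 = sigma1^2; equals (1/sigma1) exp(x^2 (1 - 1/sigma1^2) / 2).
    """
    if sigma1_sq <= 0 or sigma1_sq == 1:
        raise ValueError("sigma1_sq must be positive and != 1")
    s1 = np.sqrt(sigma1_sq)
    return float(norm.pdf(x, 0, s1) / norm.pdf(x))


def intrinsic_prior_normal(theta0: float = 0.0) -> IntrinsicConstruction:
    """Intrinsic prior for the normal location model (constant pi^O, q = 1).

    The defining integral averages the one-observation posterior
    Normal(x*, 1) over imaginary data x* ~ Normal(theta0, 1), yielding
    Normal(theta0, 2).  The resulting two-sided Bayes factor has the closed
    form (1/sqrt(3)) exp(z^2/3).
    """
    return IntrinsicConstruction(
        estimation_prior="constant",
        q=1,
        prior=PriorSpec.normal(theta0, 2.0, support_sides=2),
    )


def post_odds(prior_odds, bf: float) -> float:
    """O_post = prior odds x Bayes factor."""
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    odds = getattr(prior_odds, "odds", prior_odds)
    return float(odds * bf)


def evidence_report(z: float, prior: PriorSpec,
                    model: ModelSpec = NORMAL_LOCATION, sides: int = 1,
                    prior_odds=None) -> EvidenceReport:
    """Bundle statistic, p, m(z), R_post, the p-only bound and optional O_post."""
    p = p_from_statistic(z, sides)
    m = marginal_likelihood(prior, model, z)
    r_post = bayes_factor(prior, model, z)
    bound = bf_bound_from_p(p) if 0.0 < p < 1.0 else None
    o_post = None if prior_odds is None else post_odds(prior_odds, r_post)
    return EvidenceReport(statistic=float(z), p_value=p, marginal=m,
                          r_post=r_post, bound=bound, o_post=o_post)
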