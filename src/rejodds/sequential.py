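"""Optional stopping: naive p-value trajectories and stopping-rule-free BFs.

A proper stopping rule is a finite schedule of interim analyses ("looks")
with the guarantee that sampling ends by the last look.  Monitoring the
naive p-value of the accumulated data — recomputed at every look with no
multiplicity adjustment — inflates the frequentist Type I error above the
nominal threshold.  The Bayes factor, by contrast, is computed from the
accumulated sufficient statistic alone: the stopping rule enters the
likelihood of H0 and H1 through the same multiplicative factor and cancels,
so no function in this module ever takes the stopping rule as an argument to
a Bayes-factor computation.

Scaling convention: sample sizes are measured as fractions of the initial
sample, which has fraction 1 and is analysis 0.  After total fraction F the
sum-scale statistic S is Normal(theta F, F) under drift theta, and the usual
z-statistic is S / sqrt(F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .priors import PriorSpec

__all__ = [
    "StoppingRule",
    "SequentialSimResult",
    "simulate_naive_stopping",
    "reject_prob_vs_looks",
    "accumulated_likelihood_ratio",
    "bf_sequential",
    "simulate_stopped_bf",
]


@dataclass(frozen=True)
class StoppingRule:
    """Interim-analysis schedule with a naive p-value stopping criterion.

    ``look_fractions`` are the sizes of the batches added *after* the initial
    sample, as fractions of the initial sample size (the Example-6 pattern is
    four looks of 1/4 each).  ``final_look_always_stops`` must be True for
    the rule to be proper: sampling certainly ends at the last look.
    """

    look_fractions: tuple[float, ...]
    naive_p_threshold: float = 0.05
    sides: int = 1
    final_look_always_stops: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "look_fractions",
                           tuple(float(f) for f in self.look_fractions))
        if any(f <= 0 for f in self.look_fractions):
            raise ValueError("look fractions must be positive")
        if not (0.0 < self.naive_p_threshold < 1.0):
            raise ValueError("naive_p_threshold must be in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")

    def validate_proper(self) -> None:
        if not self.final_look_always_stops:
            raise ValueError(
                "improper stopping rule: the final look must always stop"
            )


@dataclass(frozen=True)
class SequentialSimResult:
    n_sims: int
    prob_reject: float
    mc_standard_error: float
    seed: int
    conditioned_initial_p: float | None = None


def _naive_p(z, sides: int):
    return norm.sf(z) if sides == 1 else 2 * norm.sf(np.abs(z))


def _initial_statistic(initial_p: float, sides: int) -> float:
    """z corresponding to a fixed first-look p-value (positive branch)."""
    if not (0.0 < initial_p < 1.0):
        raise ValueError("initial_p must be in (0, 1)")
    return float(norm.isf(initial_p) if sides == 1 else norm.isf(initial_p / 2))


def _simulate_paths(rule: StoppingRule, initial_p: float | None,
                    n_sims: int, seed: int):
    """Simulate sufficient-statistic paths; returns (crossed, S_stop, F_stop).

    Batch sums are exact normal draws with variance equal to each look's
    fraction — no per-observation simulation.  Paths freeze at the first
    look whose naive p-value crosses the threshold (or at the final look).
    """
    rule.validate_proper()
    rng = np.random.default_rng(seed)
    thr = rule.naive_p_threshold
    if initial_p is None:
        S = rng.standard_normal(n_sims)
        crossed = _naive_p(S, rule.sides) <= thr
    else:
        S = np.full(n_sims, _initial_statistic(initial_p, rule.sides))
        crossed = np.full(n_sims, initial_p <= thr)
    F = 1.0
    S_stop, F_stop = S.copy(), np.full(n_sims, F)
    stopped = crossed.copy()
    for f in rule.look_fractions:
        S = S + rng.normal(0.0, np.sqrt(f), n_sims)
        F += f
        live = ~stopped
        S_stop[live], F_stop[live] = S[live], F
        hit = _naive_p(S / np.sqrt(F), rule.sides) <= thr
        crossed |= hit
        stopped |= hit
    assert F_stop.max() <= 1.0 + sum(rule.look_fractions)  # proper: all stop
    return crossed, S_stop, F_stop


def simulate_naive_stopping(rule: StoppingRule, initial_p: float | None = None,
                            n_sims: int = 10**5, seed: int = 0
                            ) -> SequentialSimResult:
    """Probability under H0 that the naive p-value ever crosses the threshold.

    With ``initial_p`` given, the first analysis is conditioned on that
    p-value (fixing the initial statistic at the matching z quantile) and
    the probability refers to the later looks.
    """
    crossed, _, _ = _simulate_paths(rule, initial_p, n_sims, seed)
    p_hat = float(crossed.mean())
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_sims))
    return SequentialSimResult(n_sims=n_sims, prob_reject=p_hat,
                               mc_standard_error=se, seed=seed,
                               conditioned_initial_p=initial_p)


def reject_prob_vs_looks(look_fractions, naive_p_threshold: float = 0.05,
                         sides: int = 1, n_sims: int = 10**5,
                         seed: int = 0) -> np.ndarray:
    """Rejection probability as the number of looks grows.

    Entry k is the probability of crossing by look k (k = 0 is the single
    fixed-sample test).  All entries come from one set of simulated paths,
    so the sequence is nondecreasing by construction of the nested events.
    """
    rule = StoppingRule(tuple(look_fractions), naive_p_threshold, sides)
    rng = np.random.default_rng(seed)
    S = rng.standard_normal(n_sims)
    crossed = _naive_p(S, sides) <= naive_p_threshold
    probs = [crossed.mean()]
    F = 1.0
    for f in rule.look_fractions:
        S = S + rng.normal(0.0, np.sqrt(f), n_sims)
        F += f
        crossed |= _naive_p(S / np.sqrt(F), sides) <= naive_p_threshold
        probs.append(crossed.mean())
    return np.asarray(probs)


def accumulated_likelihood_ratio(prior: PriorSpec, S, F):
    """Bayes factor from the accumulated sufficient statistic (S, F).

    Evaluates int exp(theta S - theta^2 F / 2) pi(theta) dtheta, the
    likelihood ratio of the accumulated data under the prior to the null —
    closed forms for every prior kind, vectorized over paths.  At F = 1 and
    S = z this is exactly ``evidence.bayes_factor`` for the same prior.
    """
    S = np.asarray(S, float)
    F = np.asarray(F, float)
    if np.any(F <= 0):
        raise ValueError("total fraction F must be positive")
    z = S / np.sqrt(F)
    if prior.kind == "point":
        t1 = prior.theta1
        out = np.exp(t1 * S - t1 * t1 * F / 2.0)
    elif prior.kind == "uniform_from_null":
        a = prior.a
        root = np.sqrt(F)
        base = np.exp(z * z / 2.0) * np.sqrt(2.0 * np.pi / F)
        if prior.support_sides == 1:
            out = base * (norm.cdf(a * root - z) - norm.cdf(-z)) / a
        else:
            out = base * (norm.cdf(a * root - z) - norm.cdf(-a * root - z)) / (2 * a)
    elif prior.kind == "normal":
        mu, tau2 = prior.mean, prior.var
        denom = 1.0 + F * tau2
        out = np.exp((tau2 * S * S + 2 * mu * S - F * mu * mu) / (2 * denom)) \
            / np.sqrt(denom)
        if prior.support_sides == 1:
            v_post = tau2 / denom
            m_post = (mu + tau2 * S) / denom
            out = out * norm.sf(-m_post / np.sqrt(v_post)) \
                / norm.sf(-mu / np.sqrt(tau2))
    elif prior.kind == "grid":
        thetas = np.asarray(prior.thetas)
        w = np.asarray(prior.weights)
        expo = np.exp(S[..., None] * thetas - np.multiply.outer(F, thetas ** 2) / 2.0)
        out = expo @ w
    else:  # pragma: no cover
        raise TypeError(f"unsupported prior kind {prior.kind!r}")
    return float(out) if out.ndim == 0 else out


def bf_sequential(batches, prior: PriorSpec) -> list[float]:
    """Bayes factor after each accumulated batch.

    ``batches`` is a sequence of (z, total_fraction) pairs of the cumulative
    z-statistic and the cumulative sample fraction.  The computation uses
    only the accumulated sufficient statistic — there is deliberately no
    stopping-rule argument: the rule's indicator factor appears in both the
    numerator and denominator of the Bayes factor and cancels.
    """
    out = []
    for z, frac in batches:
        S = float(z) * np.sqrt(frac)
        out.append(float(accumulated_likelihood_ratio(prior, S, frac)))
    return out


def simulate_stopped_bf(rule: StoppingRule, prior: PriorSpec,
                        initial_p: float | None = None,
                        n_sims: int = 10**5, seed: int = 0) -> np.ndarray:
    """Final Bayes factors of paths simulated under H0 with optional stopping.

    Each path stops at its first threshold crossing (or the final look); the
    returned BF is evaluated at the stopped data.  Under H0 the BF process is
    a nonnegative martingale, so P(final BF >= k) <= 1/k.
    """
    _, S_stop, F_stop = _simulate_paths(rule, initial_p, n_sims, seed)
    return accumulated_likelihood_ratio(prior, S_stop, F_stop)
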