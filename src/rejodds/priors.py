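"""Prior (weight-function) specifications for the effect under the alternative.

A prior here plays a dual role: to a Bayesian it is the distribution of the
effect ``theta`` under H1; to a frequentist it is the weight function against
which power is averaged.  Four kinds are supported:

``point``
    all mass at a single location ``theta1 != theta0``;
``uniform_from_null``
    Uniform(theta0, theta0 + a) for one-sided support, Uniform(theta0 - a,
    theta0 + a) for two-sided — the extreme members of the nonincreasing class;
``normal``
    Normal(mean, var), optionally truncated to theta > theta0 for one-sided
    support;
``grid``
    a discrete (theta, weight) table, weights summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["PriorSpec", "parse_prior"]


@dataclass(frozen=True)
class PriorSpec:
    kind: str
    support_sides: int = 1
    theta1: float | None = None          # point location
    a: float | None = None               # uniform endpoint (distance from null)
    mean: float | None = None            # normal mean
    var: float | None = None             # normal variance
    thetas: tuple[float, ...] | None = None
    weights: tuple[float, ...] | None = None

    _KINDS = ("point", "uniform_from_null", "normal", "grid")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.support_sides not in (1, 2):
            raise ValueError("support_sides must be 1 or 2")
        if self.kind == "point":
            if self.theta1 is None:
                raise ValueError("point prior needs a location")
        elif self.kind == "uniform_from_null":
            if self.a is None or self.a <= 0:
                raise ValueError("uniform_from_null needs endpoint a > 0")
        elif self.kind == "normal":
            if self.mean is None or self.var is None or self.var <= 0:
                raise ValueError("normal prior needs mean and variance > 0")
        elif self.kind == "grid":
            if self.thetas is None or self.weights is None:
                raise ValueError("grid prior needs thetas and weights")
            w = np.asarray(self.weights, float)
            if len(self.thetas) != len(w) or len(w) == 0:
                raise ValueError("thetas and weights must have equal nonzero length")
            if np.any(w < 0):
                raise ValueError("grid weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"grid weights must sum to 1 (got {w.sum():.12g})"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def point(cls, theta1: float) -> "PriorSpec":
        return cls(kind="point", theta1=float(theta1))

    @classmethod
    def uniform_from_null(cls, a: float, support_sides: int = 1) -> "PriorSpec":
        return cls(kind="uniform_from_null", a=float(a), support_sides=support_sides)

    @classmethod
    def normal(cls, mean: float, var: float, support_sides: int = 2) -> "PriorSpec":
        return cls(kind="normal", mean=float(mean), var=float(var),
                   support_sides=support_sides)

    @classmethod
    def grid(cls, thetas, weights, support_sides: int = 1) -> "PriorSpec":
        return cls(kind="grid", thetas=tuple(float(t) for t in thetas),
                   weights=tuple(float(w) for w in weights),
                   support_sides=support_sides)

    # -- density -----------------------------------------------------------

    def pdf(self, theta, theta0: float = 0.0):
        """Prior density at ``theta`` (continuous kinds only)."""
        theta = np.asarray(theta, float)
        if self.kind == "uniform_from_null":
            if self.support_sides == 1:
                inside = (theta > theta0) & (theta <= theta0 + self.a)
                return np.where(inside, 1.0 / self.a, 0.0)
            inside = (theta >= theta0 - self.a) & (theta <= theta0 + self.a)
            return np.where(inside, 1.0 / (2 * self.a), 0.0)
        if self.kind == "normal":
            base = norm.pdf(theta, self.mean, np.sqrt(self.var))
            if self.support_sides == 1:
                # renormalized over theta > theta0
                tail = norm.sf((theta0 - self.mean) / np.sqrt(self.var))
                return np.where(theta > theta0, base / tail, 0.0)
            return base
        raise ValueError(f"{self.kind} prior has no density function")

    def support(self, theta0: float = 0.0) -> tuple[float, float]:
        """Integration bounds for the continuous kinds."""
        if self.kind == "uniform_from_null":
            if self.support_sides == 1:
                return (theta0, theta0 + self.a)
            return (theta0 - self.a, theta0 + self.a)
        if self.kind == "normal":
            sd = float(np.sqrt(self.var))
            lo = theta0 if self.support_sides == 1 else self.mean - 10 * sd
            return (lo, self.mean + 10 * sd)
        raise ValueError(f"{self.kind} prior has no continuous support")


def parse_prior(text: str) -> PriorSpec | str:
    """Parse the CLI prior grammar.

    ``point:<theta1>``, ``uniform:0:<a>``, ``normal:<mean>:<var>``,
    ``grid:<path.csv>`` (two columns theta, weight, with header),
    ``intrinsic`` and ``best-nonincreasing``.  The last two are resolved by
    the caller (they need the model or the observed statistic) and are
    returned as sentinel strings.
    """
    if text in ("intrinsic", "best-nonincreasing"):
        return text
    head, _, rest = text.partition(":")
    if head == "point":
        return PriorSpec.point(float(rest))
    if head == "uniform":
        lo, _, a = rest.partition(":")
        if float(lo) != 0.0:
            raise ValueError("uniform prior grammar is uniform:0:<a>")
        return PriorSpec.uniform_from_null(float(a))
    if head == "normal":
        mean, _, var = rest.partition(":")
        return PriorSpec.normal(float(mean), float(var))
    if head == "grid":
        import pandas as pd

        frame = pd.read_csv(rest)
        if frame.shape[1] < 2:
            raise ValueError("grid CSV needs two columns: theta, weight")
        return PriorSpec.grid(frame.iloc[:, 0], frame.iloc[:, 1])
    raise ValueError(f"cannot parse prior {text!r}")
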