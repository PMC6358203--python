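# Methods

## Setting

Everything concerns precise (point-null) testing, H0: θ = θ0 versus
H1: θ ≠ θ0 (or θ > θ0 one-sided), for data reducible to a scalar summary.
Two sampling models are implemented:

- **normal_location** — a single statistic x ~ Normal(θ, 1), θ0 = 0.  This
  is the asymptotic reduction of the common two-sample problem: a z or t
  statistic with noncentrality δ = d·√(n1·n2/(n1+n2)) for a standardized
  mean difference d.
- **normal_scale** — x ~ Normal(0, σ²), testing σ² = 1 against a simple
  alternative σ1².  Its Bayes factor is the plain likelihood ratio
  (1/σ1)·exp(x²(1 − 1/σ1²)/2), the canonical low-power example.

## Pre-experimental quantities

Power for a `TwoSampleDesign` uses the exact normal or noncentral-t tail
(df = n1 + n2 − 2); two-sided power sums both tails.  The effect size is
taken directly as the mean shift at unit variance — in particular the
benchmark 0.21 is used as d = 0.21, matching the convention of the power
tables this package reproduces (no r→d transformation).  Sidedness is an
explicit required parameter because the reference computations mix
conventions: the power table is one-sided z, the priming-study example is
two-sided t.

`power_under_prior` averages the one-observation power over the prior by
closed form (point, untruncated normal) or adaptive quadrature (uniform,
truncated normal), and a grid prior is a finite mixture.

`required_n` solves the continuous equation power(n) = target by Brent's
method and rounds to the nearest integer (minimum 2).  Rounding to nearest,
rather than taking the ceiling of the first integer whose power strictly
exceeds the target, is the convention behind printed sample-size tables
(e.g. n* = 280.39 → 280 for 80% power at effect 0.21): the half-integer
discrepancy in power is far below its reporting precision.

`solve_alpha` inverts O_pre = (π1/π0)·power/α for the significance
threshold; targets implying α ≥ 1 raise.  Probabilities are validated to
the open unit interval, except average power (may equal 1, the limiting
best case) and the hypothesis priors π0/π1 (where an extreme partner such
as π1 = 10⁻²⁰ leaves the complement indistinguishable from 1 in floating
point).

## Priors and Bayes factors

All location-model marginals m(x) = ∫ f(x|θ) π(θ) dθ have closed forms:

- point: m(x) = φ(x − θ1);
- Uniform(0, a): m(x) = [Φ(x) − Φ(x − a)]/a (symmetric two-sided variant
  on (−a, a));
- Normal(μ, τ²): m(x) = φ(x; μ, 1 + τ²), with a conjugate tail-ratio factor
  when truncated to θ > θ0;
- grid: a finite normal mixture.

The quadrature oracles in the tests confirm each closed form to 1e-6 or
better.  The supremum over all priors on θ > 0 is exp(z²/2) (point mass at
the MLE) for z > 0 and 1 in the limit θ → θ0⁺ for z ≤ 0; no mass is ever
placed on the null value itself.  The most favorable nonincreasing prior is
found by bounded scalar maximization of the Uniform(0, a) Bayes factor over
a ∈ (1e-6, z + 10] with absolute tolerance 1e-6; its printed argmax 2.95 is
matched at two decimals (the true argmax is 2.9478).

The intrinsic prior for the location model starts from the constant
estimation prior, updates it with a minimal imaginary sample (q = 1) drawn
under the null, and averages: the result is Normal(θ0, 2), giving the
closed-form default Bayes factor (1/√3)·exp(z²/3).

`bf_bound_from_p` implements 1/(−e·p·ln p) with the natural log and
returns an explicit `None` for p > 1/e rather than extrapolating the
formula outside its validity.

### Accuracy of the bound for normal priors

The bound is exact for alternatives whose p-value density is Beta(1, b)
and under a hazard-rate condition more generally; the normal location
class satisfies it only approximately.  Numerically, the best
nonincreasing prior exceeds the bound one-sided from moderate z on (5.63
vs 4.76 at z = 2.06), and even the symmetric two-sided class crosses the
bound near z ≈ 2.4, by ~3% at z = 3 and ~8% at z = 5.  The tests therefore
assert exact domination only in the moderate-evidence two-sided zone
(z ≤ 2.1, where the comparison is tight: 2.883 ≤ 2.887 at z = 2.06) and a
bounded minor excess elsewhere (≤ 12% two-sided, below a factor of two
one-sided, for z ≤ 6).

## Calibration identities

For any prior, E[R_post(z) | H0, rejection] = R_pre and
E[1/R_post(z) | H1*, rejection] = 1/R_pre, H1* being the marginal
alternative with density m.  Verification is by deterministic adaptive
quadrature over the rejection region; the integrand of the first identity
collapses analytically to m(z) (taming the heavy right tail of R_post
under point priors), and the second identity's integrand is cut off where
the null density underflows (|z| > 37, residual mass < 1e-17) and guarded
where CDF differences underflow to zero.  Both identities verify to
relative error < 1e-5 across point/uniform/normal priors, α ∈
{0.10, 0.05, 0.01, 0.005}, one- and two-sided; α = 1 (rejection region =
whole line) is admitted as the trivial case where both expectations are
exactly 1.  A rejection-sampled Monte Carlo check (inverse-CDF truncation,
10⁶ draws, fixed seed) agrees within four standard errors.

## Optional stopping

Simulation operates on normal sufficient statistics: sample sizes are
fractions of the initial sample (the initial sample is fraction 1 and is
analysis 0), each added batch contributes an exact Normal(0, f) increment
to the sum-scale statistic S, and after total fraction F the naive
z-statistic of the accumulated data is S/√F, its p-value recomputed with no
adjustment ("reaching" the threshold means p ≤ threshold; ties are
measure-zero).  Conditioning on an initial p-value fixes the first
statistic at the matching quantile.  Rules are finite schedules whose last
look always stops (properness); an improper rule raises.  A single seeded
generator drives each run and the seed is recorded in the result.

The curve of rejection probability versus number of looks is computed from
one set of nested paths, so it is exactly monotone; with 19 added
quarter-batches the crossing probability reaches ~0.18, more than triple
the nominal 5%.
Conditioned on an initial p = 0.08 with four added quarter-batches, the
crossing probability is 0.358 (one-sided) or 0.335 (two-sided) at 10⁶
paths — reported under both conventions because the sidedness of the
motivating example is not fixed by its statement; see the known-limitations
note below.

The stopped-data Bayes factor is computed from (S, F) alone via
∫ exp(θS − θ²F/2) π(θ) dθ in closed form per prior kind.  No stopping-rule
argument exists anywhere in the Bayes-factor path: the rule's indicator
factor multiplies the stopped-data likelihood of both hypotheses and
cancels (verified path-by-path to 1e-12 against the explicit joint-density
ratio).  Under H0 this likelihood ratio is a nonnegative martingale, so
P(stopped BF ≥ k) ≤ 1/k regardless of the rule — checked by simulation for
k ∈ {2, 5, 10, 20}.

## Reference tables and printed precision

`tables.reproduce_table` regenerates the five reference tables from the
core.  "Match at printed precision" means the computed value lies within
one unit in the last printed place — the printed tables mix rounding and
truncation (e.g. a bound of 53.2560 printed as 53.25), and cells printed
loosely (large integers, scientific notation) are compared at two
significant figures.  Under this rule the ratio, power and variance-test
tables (1, 2, 4, 5) regenerate with zero mismatches.

The bound table (3) does not: its cells at p = 0.05, 0.01 and 0.001 print
2.44, 8.13 and 52.9 where the formula (confirmed independently by table
4's bound row) gives 2.456, 7.988 and 53.256 — within 3% — and its two
genome-wide cells print 2.0×10⁵ and 2.3×10⁶ where the formula gives
5.07×10⁴ and 4.38×10⁵, a factor of 4–5.  All five cells are flagged as
mismatches and left as documented discrepancies; nothing is silently
corrected.

## Known limitations

- The motivating optional-stopping example's claimed crossing probability
  of 2/3 is not recovered under any natural reading of its setup (both
  sidedness conventions, several batch layouts give 0.25–0.63); the
  simulator reports the conventions explicitly instead of matching the
  figure, and the Type I inflation it illustrates is fully reproduced.
- The "study team" subjective prior of the vaccine example is not publicly
  specified; its R_post = 4.0 (and the 35:1 value at z = 3) are therefore
  outside scope, as are re-analyses of published Bayes factor collections
  and composite-null invariance reductions.
- Binary-outcome power is not re-derived from trial counts: the vaccine
  design's average power 0.45 is an input, as in the original analysis.
- Welch (unequal-variance) designs, cluster designs and non-normal
  likelihoods are out of scope.
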