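# rejodds

Rejection odds and rejection ratios for precise hypothesis testing.

When a study tests a point null H0: θ = θ0 against H1: θ ≠ θ0, a bare
"p < 0.05" says little about how likely the rejection was to be correct.
`rejodds` computes the quantities that do:

- **Pre-experimental rejection ratio** — R_pre = (1 − β̄)/α, the ratio of
  (prior-averaged) power to the Type I error: the odds that a significant
  result arises under H1 rather than H0 at even prior odds.  The
  pre-experimental odds are O_pre = (π1/π0) · R_pre.
- **Post-experimental rejection ratio (Bayes factor)** —
  R_post(x) = m(x)/f(x|θ0) with m(x) = ∫ f(x|θ) π(θ) dθ, under point,
  uniform-from-null, normal (incl. the intrinsic Normal(θ0, 2)), or grid
  priors; the posterior odds are O_post = (π1/π0) · R_post(x).
- **The p-value-only bound** — R_post(x) ≤ 1/(−e p ln p) for p ≤ 1/e:
  the best case for H1 computable from a p-value alone.
- **Frequentist calibration** — numerical verification that
  E[R_post | H0, rejection] = R_pre and E[1/R_post | H1*, rejection] =
  1/R_pre for any prior, by quadrature with a Monte Carlo cross-check.
- **Optional stopping** — simulation of naive p-value monitoring (Type I
  inflation) versus the stopped Bayes factor, which ignores the stopping
  rule and obeys P(BF ≥ k | H0) ≤ 1/k.

The library targets researchers planning or appraising significance tests:
the inputs are scalar summaries (effect sizes, group sizes, z/t statistics,
p-values, 2×2 counts), never raw datasets.

## Worked example

A vaccine trial observed 74 infections among 8198 placebo recipients and
51 among 8197 vaccinated:

```python
from rejodds import (bf_best_nonincreasing, bf_sup_all_priors,
                     p_from_statistic, rejection_ratio, z_from_counts)

z = z_from_counts(74, 8198, 51, 8197)
print(round(z, 2))                       # 2.06
print(round(p_from_statistic(z, 1), 2))  # 0.02
print(rejection_ratio(0.45, 0.05))       # 9.0  (designed power 0.45)
a, bf = bf_best_nonincreasing(2.06)
print(round(a, 2), round(bf, 2))         # 2.95 5.63
print(round(bf_sup_all_priors(2.06), 2)) # 8.35
```

The design promised 9:1 odds for a rejection; the data actually observed
support at most 8.35:1 under *any* prior, and 5.63:1 under the
nonincreasing prior most favorable to the vaccine — so reading the p-value
of 0.02 as "50:1" evidence overstates the case by an order of magnitude.

The same computations are available from the shell:

```bash
rejodds design --effect 0.21 --n1 280 --n2 280 --alpha 0.05 --sides 1 --family z
rejodds bf --counts 74:8198:51:8197 --prior best-nonincreasing
rejodds bound --p 0.05
rejodds calibrate --prior point:1.519 --alpha 0.05 --sides 1
rejodds stopping --initial-p 0.08 --looks 0.25,0.25,0.25,0.25 --seed 1
rejodds tables --which 2
```

and `examples/` contains one narrative script per capability.

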