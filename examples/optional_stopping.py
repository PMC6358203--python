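"""Optional stopping cheats p-values but not Bayes factors.

Starting from p = 0.08 on the initial sample, peeking four more times
(adding a quarter of the sample each time, testing the accumulated data at
the naive 0.05 threshold) rejects a true null far more often than 5%.  The
stopped Bayes factor, by contrast, obeys P(BF >= k | H0) <= 1/k no matter
the stopping rule.
"""

import numpy as np

from rejodds import (
    PriorSpec,
    StoppingRule,
    simulate_naive_stopping,
    simulate_stopped_bf,
)

rule = StoppingRule(look_fractions=(0.25, 0.25, 0.25, 0.25),
                    naive_p_threshold=0.05, sides=1)

res = simulate_naive_stopping(rule, initial_p=0.08, n_sims=200_000, seed=1)
print(f"P(reach p <= 0.05 at some look | p0 = 0.08, H0) = "
      f"{res.prob_reject:.3f} +/- {res.mc_standard_error:.3f}")

unconditional = simulate_naive_stopping(rule, None, n_sims=200_000, seed=1)
print(f"unconditional rejection probability with 5 looks = "
      f"{unconditional.prob_reject:.3f} (nominal 0.05)")

bfs = simulate_stopped_bf(rule, PriorSpec.uniform_from_null(2.95),
                          n_sims=200_000, seed=1)
for k in (2, 5, 10, 20):
    print(f"P(stopped BF >= {k:2d} | H0) = {np.mean(bfs >= k):.4f}  "
          f"(martingale bound {1/k:.3f})")
print("\nThe naive p-value treats every peek as a fresh 5% chance; the "
      "Bayes factor is unchanged by the peeking.")
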