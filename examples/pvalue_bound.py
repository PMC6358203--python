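"""What a p-value can and cannot say: the bound 1/(-e p ln p).

The largest Bayes factor compatible with a given p-value (under natural
conditions on the alternative) needs nothing but the p-value itself.  A
'significant' p = 0.05 caps the evidence at about 2.5:1 — far from the 20:1
that misreading 1/p would suggest.
"""

from rejodds import bf_bound_from_p

for p in (0.1, 0.05, 0.01, 0.005, 0.001):
    bound = bf_bound_from_p(p)
    print(f"p = {p:<6}  max R_post = {bound:7.2f}:1")

print(f"\np = 0.5 -> bound: {bf_bound_from_p(0.5)} "
      "(the formula applies only for p <= 1/e)")
print("p = 0.005 is the threshold whose best case is ~14:1, close to the "
      "16:1 convention of 80% power at alpha = 0.05.")
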