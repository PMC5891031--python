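"""The four-state duplicate-loss model and its transition probabilities.

Every post-WGD locus starts as an undifferentiated duplicate pair (U) and is
eventually fixed as a permanent duplicate (F, rate gamma) or returned to
single copy, keeping the subgenome-1 copy (S1, rate 1) or the subgenome-2
copy (S2, rate epsilon <= 1).  Branch lengths are alpha*t: base loss rate
times time.
"""

import numpy as np

from wgdresolve import rate_matrix, transition_probs, STATES

gamma, eps = 0.169, 0.645  # bias and fixation at plant-paleopolyploidy scale

print("Generator Q (rows/cols:", ", ".join(STATES), ")")
print(np.round(rate_matrix(gamma, eps), 3))

for b in (0.1, 0.5, 2.0):
    p = transition_probs(gamma, eps, b)
    print(f"\nP(branch length {b}) row U:", np.round(p[0], 4))
    print(f"  P(U->S2)/P(U->S1) = {p[0, 3] / p[0, 2]:.3f}  (= epsilon: the "
          "expected ratio of single-copy genes retained from subgenome 2 "
          "vs subgenome 1)")
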