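"""Search for the strict-Saaty judgment matrix behind printed priorities.

The study printed its priority vectors but not the pairwise judgment
matrices they came from. For a 3-alternative criterion the 17^3 possible
upper triangles can be searched exhaustively; for larger criteria a
deterministic greedy search refines the rounded consistent start.
"""

import numpy as np

from ahprank import PriorityVector, fit_saaty_matrix

# mole ratio: printed priorities 81.8 / 9.1 / 9.1 (%)
target = PriorityVector.from_raw(["1:3", "1:2.5", "1:2"], [0.818, 0.091, 0.091])
m, residual = fit_saaty_matrix(target, budget=17**3)
print("mole-ratio criterion (exhaustive search):")
print(np.array_str(m.values, precision=3))
print(f"residual = {residual:.2e}\n")

# criterion weights: printed 33.1 / 33.1 / 23.7 / 10.1 (%)
target4 = PriorityVector(["metal_salt", "mole_ratio", "solvent", "duration"],
                         [0.331, 0.331, 0.237, 0.101])
m4, residual4 = fit_saaty_matrix(target4)
print("criterion weights (greedy search):")
print(np.array_str(m4.values, precision=3))
print(f"residual = {residual4:.4f}")

# The mole-ratio fit lands on the unique consistent matrix (9, 9, 1) with
# near-zero residual. The criterion-weight target is NOT exactly
# representable on the 1-9 scale (33.1/23.7 ~ 1.40 sits between scale
# points), so the best strict-Saaty matrix keeps a small residual — the
# printed weights most likely came from unrounded or aggregated judgments.
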