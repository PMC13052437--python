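"""Derive criterion and alternative priorities for the porphyrin study.

Loads the packaged Pd(II)/Pt(II) metalation hierarchy, prints each
priority vector in percent, and shows the consistency diagnostics of the
one judgment matrix the model reconstructs (mole ratio). A consistency
ratio (CR) of 0 means the judgments are perfectly transitive.
"""

from ahprank import consistency, load_porphyrin_hierarchy

h = load_porphyrin_hierarchy()
print(f"goal: {h.goal}\n")

print("criterion weights (%):")
for lab, w in zip(h.criteria_weights.labels, h.criteria_weights.weights):
    print(f"  {lab:12s} {100 * w:5.1f}")

for c in h.criteria:
    print(f"\n{c.name} alternatives (%):  [{c.provenance}]")
    for lab, w in zip(c.priorities.labels, c.priorities.weights):
        note = "  (imputed)" if lab in c.imputed else ""
        print(f"  {lab:20s} {100 * w:5.1f}{note}")
    if c.matrix is not None:
        rep = consistency(c.matrix)
        print(f"  matrix: lambda_max={rep.lambda_max:.3f}  CR={rep.cr:.3f}  "
              f"consistent={rep.consistent}")

# Metal salt and mole ratio dominate the decision (33.1% each); the 1:3
# ratio carries 81.8% of its criterion's weight, so combinations using it
# are strongly favoured.
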