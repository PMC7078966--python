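"""Benefit-risk curves: how much harm buys how much benefit.

Fix a benefit margin (here: beat competitors on efficacy by at least 0.2
SMD) and sweep a tolerance on the risk outcome (weight gain, oriented so
negative CIVs tolerate a deficit).  Each treatment's curve shows its joint
P-score as the tolerated harm grows; crossings mark the tolerance at which
one treatment's benefit-risk profile overtakes another's.
"""

from civrank import CivSpec, benefit_risk_curves, find_crossings, load_example_network

je = load_example_network()

curves = benefit_risk_curves(
    je,
    benefit_outcome="efficacy",
    risk_outcome="weight_gain",
    benefit_civ=0.2,
    risk_grid=CivSpec.from_range("weight_gain", -1.0, 0.0, 0.05),
)

top = sorted(curves.treatments, key=lambda t: -curves.curve(t)[0])[:4]
print("joint P-score vs tolerated weight-gain deficit "
      "(benefit margin fixed at 0.2 SMD):")
print("tolerance  " + "  ".join(f"{t:>8}" for t in top))
for g in range(0, curves.grid.size, 4):
    row = "  ".join(f"{curves.curve(t)[g]:8.3f}" for t in top)
    print(f"{curves.grid[g]:9.2f}  {row}")

a, b = top[0], top[1]
xs = find_crossings(curves, (a, b))
if xs:
    print(f"\n{a} and {b} swap order at tolerance CIV = {xs[0]:.3f}")
else:
    print(f"\n{a} stays ahead of {b} over the whole tolerance range")
print("(more negative tolerance = more weight gain accepted in exchange "
      "for the efficacy margin)")
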