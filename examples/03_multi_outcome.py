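"""Joint P-scores over several outcomes.

The joint P-score of a treatment averages, over its competitors, the
probability of beating them on all outcomes simultaneously — a
multivariate-normal orthant probability whose between-outcome correlation
must be supplied (here the packaged illustrative matrix: efficacy and
acceptability reinforce each other at +0.5, both at -0.5 against avoiding
weight gain).  Scores shrink as outcomes are added, because beating a
competitor everywhere is harder than beating it anywhere.
"""

from civrank import load_example_network, multi_pscores, pscores, table1_style_report

je = load_example_network()

single = {oc.outcome_name: pscores(oc).scores for oc in je.outcomes}
two = multi_pscores(je.subset(("efficacy", "discontinuation")))
three = multi_pscores(je)

print(f"{'treatment':<10} {'efficacy':>9} {'eff+acc':>9} {'all three':>10}")
for i, t in enumerate(je.treatments):
    print(f"{t:<10} {single['efficacy'][i]:9.3f} {two.scores[i]:9.3f} "
          f"{three.scores[i]:10.3f}")

print("\nTable-style report (percentages, ranks):")
print(table1_style_report(je).to_string(index=False))
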