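"""Score a structure-odor rule on the packaged six-molecule dataset.

The rule restricts molecular weight, atom count and carbon count, and
targets the 'vanillin' quality.  Printed: the covered molecules, how many
of them carry the quality, and the resulting precision / recall / F1 —
the fraction of covered molecules that smell of vanillin, the fraction of
vanillin molecules the rule reaches, and their harmonic mean.
"""

from odormine import Description, SORule, coverage, evaluate, toy_dataset

ds = toy_dataset()
rule = SORule(
    Description((("MW", 128, 151), ("nAT", 23, 29), ("nC", 9, 12))),
    frozenset({"vanillin"}),
)

print("rule: MW in [128,151] & nAT in [23,29] & nC in [9,12] -> vanillin")
print("coverage:", coverage(rule.description, ds))
m = evaluate(rule, ds)
print(f"positives in coverage: {m.positives_in_coverage} of {m.support_d} covered")
print(f"support of vanillin:   {m.support_q} of {ds.n_molecules} molecules")
print(f"precision = {m.precision:.4f}   recall = {m.recall:.4f}   F1 = {m.f1:.4f}")
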