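"""Full selection pipeline on the six-molecule dataset.

Mines rules for every quality at two minimum-support thresholds, selects
the rule combination closest to the ideal (error 0, recall 1) point per
quality, assigns distance quartiles, and bootstrap-tests each selection
against random same-size molecule samples.  A 'significant' verdict means
the selected rules describe their quality better than the 99% upper bound
of chance coverage.  On six molecules random samples often reach a perfect
F too, so the verdicts here are honestly negative — the bootstrap needs a
corpus-scale dataset to have power (see examples/mine_synthetic.py).
"""

from odormine import (
    MinerConfig,
    assign_quartiles,
    batch_significance,
    mine_all,
    select_best,
    selection_report,
    toy_dataset,
)

ds = toy_dataset()
runs_by_min_supp = {
    s: mine_all(ds, MinerConfig(min_supp=s, beam_width=30, max_properties=3,
                                max_output=20))
    for s in (2, 3)
}

results = []
for quality in sorted({q for runs in runs_by_min_supp.values() for q in runs},
                      key=sorted):
    pools = {
        s: [rule for rule, _ in runs[quality].rules]
        for s, runs in runs_by_min_supp.items()
        if quality in runs
    }
    results.append(select_best(pools, quality, ds, max_rules=12))
assign_quartiles(results)

print(selection_report(results).to_string(index=False))
table = batch_significance(results, ds, n_resamples=10_000, seed=1, measure="f1")
print(table[["quality", "X", "observed_F", "ci_high", "significant"]]
      .to_string(index=False))
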