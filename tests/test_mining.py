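"""Beam search mining: refinement operator, constraints, oracle equivalence."""

import json

import numpy as np
import pytest

from odormine import (
    Description,
    MinerConfig,
    OdorantDataset,
    enumerate_targets,
    generate,
    mine,
    mine_all,
    recovery_score,
    refinements,
    ruleset_from_json,
    ruleset_to_json,
    benchmark_spec,
)
from oracles import exhaustive_best_f_beta, random_small_dataset

TOY_CFG = MinerConfig(min_supp=2, max_supp=700, beam_width=30, max_properties=3)


class TestEnumerateTargets:
    def test_singletons_above_support(self, toy):
        assert enumerate_targets(toy, max_qual=1, min_supp=2) == [
            frozenset({"fruity"}),
            frozenset({"vanillin"}),
            frozenset({"woody"}),
        ]

    def test_support_threshold_prunes_everything(self, toy):
        assert enumerate_targets(toy, max_qual=1, min_supp=5) == []

    def test_pairs_include_cooccurring_labels(self, toy):
        targets = enumerate_targets(toy, max_qual=2, min_supp=2)
        assert frozenset({"fruity", "vanillin"}) in targets  # molecules 5 and 6
        assert frozenset({"vanillin", "woody"}) not in targets  # support 1


class TestRefinements:
    def test_lower_bound_steps_to_next_observed_value(self, toy):
        refs = refinements(Description(), toy, max_properties=3)
        mw_lo = [d for d in refs if d.conditions[0].descriptor == "MW"
                 and d.conditions[0].lo > 128]
        assert mw_lo[0].conditions[0] .lo == 136
        assert mw_lo[0].conditions[0].hi == 152

    def test_max_properties_blocks_new_descriptors(self, toy):
        desc = Description((("MW", 128, 151),))
        refs = refinements(desc, toy, max_properties=1)
        assert all(d.restricted_descriptors == ("MW",) for d in refs)

    def test_single_distinct_value_not_refined(self):
        ds = OdorantDataset(
            ["a", "b"], ["x", "y"], [[1.0, 2.0], [1.0, 5.0]],
            {"a": frozenset({"q"}), "b": frozenset({"q"})},
        )
        refs = refinements(Description(), ds, max_properties=2)
        assert all(d.restricted_descriptors == ("y",) for d in refs)

    def test_refinements_never_empty_coverage(self, toy):
        from odormine import coverage

        for d in refinements(Description(), toy, max_properties=3):
            assert len(coverage(d, toy)) > 0


class TestMine:
    def test_toy_beam_attains_exhaustive_optimum(self, toy):
        run = mine(toy, {"vanillin"}, TOY_CFG)
        best = run.rules[0][1].f_beta
        oracle = exhaustive_best_f_beta(toy, {"vanillin"}, min_supp=2, max_properties=3)
        assert best == pytest.approx(oracle)

    def test_all_positive_target_yields_perfect_unrestricted_rule(self):
        ids = [str(i) for i in range(6)]
        ds = OdorantDataset(
            ids, ["x"], np.arange(6, dtype=float).reshape(-1, 1),
            {m: frozenset({"q"}) for m in ids},
        )
        run = mine(ds, {"q"}, MinerConfig(min_supp=1, beam_width=5))
        rule, m = run.rules[0]
        assert rule.description.conditions == ()
        assert (m.precision, m.recall, m.f_beta) == (1.0, 1.0, 1.0)

    def test_planted_box_recovered(self):
        spec = benchmark_spec(7)
        ds, _ = generate(spec)
        cfg = MinerConfig(
            min_supp=10, beam_width=30, max_properties=8,
            x_beta=40, l_beta=20, refinement_grid="quantiles:16",
        )
        run = mine(ds, {"planted"}, cfg)
        assert recovery_score(run.rules, spec.planted_rules[0], ds) >= 0.8

    def test_unknown_quality_rejected(self, toy):
        with pytest.raises(KeyError):
            mine(toy, {"metallic"}, TOY_CFG)

    def test_emitted_rules_respect_all_constraints(self):
        """Every emitted rule satisfies minSupp <= support <= maxSupp and
        the maxProperties cap, over 100 random synthetic instances."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            ds = random_small_dataset(rng, n_molecules=int(rng.integers(8, 20)))
            cfg = MinerConfig(
                min_supp=int(rng.integers(1, 4)),
                max_supp=int(rng.integers(6, 15)),
                max_properties=int(rng.integers(1, 3)),
                beam_width=int(rng.integers(2, 8)),
                max_output=10,
            )
            run = mine(ds, {"q0"}, cfg)
            assert len(run.rules) <= cfg.max_output
            fbs = [m.f_beta for _, m in run.rules]
            assert fbs == sorted(fbs, reverse=True)
            for rule, m in run.rules:
                assert cfg.min_supp <= m.support_d <= cfg.max_supp
                assert len(rule.description) <= cfg.max_properties

    def test_ranking_invariant_to_row_order(self):
        rng = np.random.default_rng(23)
        ds = random_small_dataset(rng, n_molecules=12, n_descriptors=2)
        perm = rng.permutation(12)
        shuffled = OdorantDataset(
            [ds.molecule_ids[i] for i in perm],
            ds.descriptor_names,
            ds.values[perm],
            {m: ds.labels[m] for m in ds.molecule_ids},
        )
        cfg = MinerConfig(min_supp=2, beam_width=5, max_properties=2, max_output=20)
        a, b = mine(ds, {"q0"}, cfg), mine(shuffled, {"q0"}, cfg)
        assert ruleset_to_json(a.rules) == ruleset_to_json(b.rules)

    def test_raising_min_supp_shrinks_feasible_set(self):
        rng = np.random.default_rng(31)
        ds = random_small_dataset(rng, n_molecules=10, n_descriptors=2)
        big = 10**6
        cfg_lo = MinerConfig(min_supp=2, beam_width=big, max_properties=2, max_output=big)
        cfg_hi = MinerConfig(min_supp=5, beam_width=big, max_properties=2, max_output=big)
        cov_lo = {(m.support_d, m.positives_in_coverage)
                  for _, m in mine(ds, {"q0"}, cfg_lo).rules}
        rules_hi = mine(ds, {"q0"}, cfg_hi).rules
        assert all(m.support_d >= 5 for _, m in rules_hi)
        # every rule feasible at the stricter threshold was feasible at the looser one
        assert {(m.support_d, m.positives_in_coverage) for _, m in rules_hi} <= cov_lo


class TestMineAll:
    def test_toy_yields_three_runs(self, toy):
        runs = mine_all(toy, TOY_CFG)
        assert set(runs) == {
            frozenset({"fruity"}), frozenset({"vanillin"}), frozenset({"woody"})
        }

    def test_empty_dataset_yields_empty_mapping(self):
        ds = OdorantDataset([], ["x"], np.empty((0, 1)), {})
        assert mine_all(ds, TOY_CFG) == {}

    def test_bitwise_reproducible_across_reruns(self, toy):
        a = {"+".join(sorted(q)): ruleset_to_json(r.rules)
             for q, r in mine_all(toy, TOY_CFG).items()}
        b = {"+".join(sorted(q)): ruleset_to_json(r.rules)
             for q, r in mine_all(toy, TOY_CFG).items()}
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestSerialization:
    def test_rule_json_round_trip_is_exact(self, toy):
        rules = mine(toy, {"vanillin"}, TOY_CFG).rules
        payload = json.dumps(ruleset_to_json(rules))
        back = ruleset_from_json(json.loads(payload))
        assert ruleset_to_json(back) == ruleset_to_json(rules)

    def test_yaml_config_accepts_printed_parameter_names(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "maxoutput: 100\nbeamwidth: 30\nMaxQual: 1\nMaxProperties: 8\n"
            "maxSupp: 700\nXBeta: 110\nlBeta: 20\nminSupp: 5\n"
        )
        cfg = MinerConfig.from_yaml(cfg_file)
        assert (cfg.max_output, cfg.beam_width, cfg.max_qual) == (100, 30, 1)
        assert (cfg.max_properties, cfg.max_supp) == (8, 700)
        assert (cfg.x_beta, cfg.l_beta, cfg.min_supp) == (110, 20, 5)

    def test_unknown_config_key_rejected(self, tmp_path):
        cfg_file = tmp_path / "bad.yaml"
        cfg_file.write_text("minSupp: 5\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            MinerConfig.from_yaml(cfg_file)


@pytest.mark.parametrize("bad", [
    dict(min_supp=0),
    dict(min_supp=10, max_supp=5),
    dict(beam_width=0),
    dict(refinement_grid="grid:oops"),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        MinerConfig(**bad)
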