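import numpy as np
import pytest

import _oracles as oracle
from conftest import random_gene_tree
from phylocurate.contamination import (
    CladeRule,
    Phase,
    RuleError,
    SisterRule,
    SubsisterRule,
    apply_sister_rules,
    apply_subsister_rules,
    clade_grab,
    read_clade_rules,
    read_sister_rules,
    run_loop,
)
from phylocurate.tree_engine import GeneTree


def _gt(newick):
    return GeneTree.from_newick_string(newick)


class TestSisterRules:
    def test_food_source_rule_fires(self, favella_tree):
        rule = SisterRule("r1", "Sr_ci_Fehr", ("EE_ha",), "any")
        removed = apply_sister_rules(favella_tree, [rule])
        assert [r.seq_id for r in removed] == ["Sr_ci_Fehr_c1_OG6_000001"]
        assert removed[0].mode == "sister"
        assert "EE_ha_Ehux" in removed[0].observed_context

    def test_short_branch_threshold(self, favella_tree):
        # mean terminal branch = (0.01+0.01+0.1)/3 = 0.04; threshold 0.02
        rule = SisterRule("r1", "Sr_ci_Fehr", ("EE_ha",), "short", 0.5)
        removed = apply_sister_rules(favella_tree, [rule])
        assert len(removed) == 1
        assert removed[0].threshold_applied == pytest.approx(0.02)
        longer = _gt(
            "((Sr_ci_Fehr_c1_OG6_000001:0.05,EE_ha_Ehux_c1_OG6_000001:0.01):0.1,"
            "Sr_ci_Tthe_c1_OG6_000001:0.1);"
        )
        assert apply_sister_rules(longer, [rule]) == []

    def test_mixed_sister_group_blocks_rule(self):
        t = _gt(
            "((Sr_ci_Fehr_c1_OG6_000001:0.01,(EE_ha_Ehux_c1_OG6_000001:0.01,"
            "Sr_ci_Tthe_c1_OG6_000001:0.01):0.01):0.1,Ba_pr_S001_c1_OG6_000001:0.1);"
        )
        rule = SisterRule("r1", "Sr_ci_Fehr", ("EE_ha",), "any")
        assert apply_sister_rules(t, [rule]) == []

    def test_same_target_cherry_is_not_single_sequence(self):
        # two leaves of the rule's target forming the cherry: subsister territory
        t = _gt(
            "((Sr_ci_Fehr_c1_OG6_000001:0.01,Sr_ci_Fehr_c2_OG6_000001:0.01):0.1,"
            "EE_ha_Ehux_c1_OG6_000001:0.1);"
        )
        rule = SisterRule("r1", "Sr_ci_Fehr", ("EE_ha",), "any")
        assert apply_sister_rules(t, [rule]) == []

    def test_rule_validation(self):
        with pytest.raises(RuleError):
            SisterRule("r1", "Sr_ci", ())
        with pytest.raises(RuleError):
            SisterRule("r1", "Sr_ci", ("Ba",), "short", -1.0)


class TestSubsisterRules:
    def test_co_contaminant_pair_removed(self):
        t = _gt(
            "(((Op_ap_Ains_c1_OG6_000001,Op_ap_Atri_c1_OG6_000001),"
            "Am_tu_Hp01_c1_OG6_000001),Ba_pr_S001_c1_OG6_000001);"
        )
        rule = SubsisterRule("ss1", ("Op_ap_Ains", "Op_ap_Atri"), ("non-Op",))
        removed = apply_subsister_rules(t, [rule])
        assert sorted(r.seq_id for r in removed) == [
            "Op_ap_Ains_c1_OG6_000001", "Op_ap_Atri_c1_OG6_000001"
        ]

    def test_opisthokont_sister_blocks_complement_rule(self):
        t = _gt(
            "(((Op_ap_Ains_c1_OG6_000001,Op_ap_Atri_c1_OG6_000001),"
            "Op_fu_Scer_c1_OG6_000001),Ba_pr_S001_c1_OG6_000001);"
        )
        rule = SubsisterRule("ss1", ("Op_ap_Ains", "Op_ap_Atri"), ("non-Op",))
        assert apply_subsister_rules(t, [rule]) == []

    def test_pair_not_a_cherry_no_firing(self):
        t = _gt(
            "((Op_ap_Ains_c1_OG6_000001,(Op_ap_Atri_c1_OG6_000001,"
            "Am_tu_Hp01_c1_OG6_000001)),Ba_pr_S001_c1_OG6_000001);"
        )
        rule = SubsisterRule("ss1", ("Op_ap_Ains", "Op_ap_Atri"), ("non-Op",))
        assert apply_subsister_rules(t, [rule]) == []

    def test_pair_must_differ(self):
        with pytest.raises(RuleError):
            SubsisterRule("ss1", ("Op_ap_Ains", "Op_ap_Ains"), ("non-Op",))


class TestCladeGrab:
    def _tree_with_strays(self):
        core = ",".join(f"Sr_ci_S{i:03d}_c{i}_OG6_000002:0.1" for i in range(12))
        return _gt(
            f"((({core}):0.1,(Sr_ci_S900_c90_OG6_000002:0.1,"
            "Ex_pa_S001_c1_OG6_000002:0.1):0.1):0.1,"
            "((Sr_ci_S901_c91_OG6_000002:0.1,Ba_pr_S001_c1_OG6_000002:0.1):0.1,"
            "(Sr_ci_S902_c92_OG6_000002:0.1,Ba_pr_S002_c2_OG6_000002:0.1):0.1):0.1);"
        )

    def test_strays_removed_clade_kept(self):
        t = self._tree_with_strays()
        rule = CladeRule("c1", "Sr_ci", min_target=12, nontarget_allowance=0)
        kept, removals = clade_grab(t, [rule])
        removed = {r.seq_id for r in removals}
        assert removed == {
            "Sr_ci_S900_c90_OG6_000002", "Sr_ci_S901_c91_OG6_000002",
            "Sr_ci_S902_c92_OG6_000002",
        }
        assert all(lab.startswith("Sr_ci_S0") or not lab.startswith("Sr_ci")
                   for lab in kept)

    def test_exception_prefix_spared(self):
        t = self._tree_with_strays()
        rule = CladeRule("c1", "Sr_ci", 12, 0, exceptions=("Sr_ci_S900",))
        _, removals = clade_grab(t, [rule])
        assert "Sr_ci_S900_c90_OG6_000002" not in {r.seq_id for r in removals}

    def test_unreachable_min_target_removes_all_targets(self):
        t = self._tree_with_strays()
        rule = CladeRule("c1", "Sr_ci", min_target=50)
        kept, removals = clade_grab(t, [rule])
        assert all(not lab.startswith("Sr_ci") for lab in kept)

    def test_nontarget_never_removed(self, rng):
        for _ in range(10):
            t = random_gene_tree(rng)
            _, removals = clade_grab(t, [CladeRule("c1", "Op_me", 3, 0)])
            assert all(r.seq_id.startswith("Op_me") for r in removals)

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            t = random_gene_tree(rng)
            for min_target, allowance in ((1, 0), (2, 0), (3, 1), (2, 0.34)):
                rule = CladeRule("c", "Op_me", min_target, allowance)
                _, removals = clade_grab(t, [rule])
                assert {r.seq_id for r in removals} == oracle.brute_clade_grab_removed(
                    t, rule
                )

    def test_monotonicity(self, rng):
        for _ in range(10):
            t = random_gene_tree(rng)
            kept_sizes = []
            for m in (1, 2, 4, 8):
                kept, _ = clade_grab(t, [CladeRule("c", "Op_me", m, 0)])
                kept_sizes.append(len(kept))
            assert kept_sizes == sorted(kept_sizes, reverse=True)
            kept_narrow, _ = clade_grab(t, [CladeRule("c", "Op_me", 2, 0)])
            kept_wide, _ = clade_grab(t, [CladeRule("c", "Op_me", 2, 2)])
            assert set(kept_narrow) <= set(kept_wide)


class TestRunLoop:
    def test_chain_of_contaminants_converges(self):
        # removing the innermost contaminant exposes the next one
        t = _gt(
            "(((((Sr_ci_S001_c1_OG6_000003:0.01,Ba_pr_S001_c1_OG6_000003:0.1):0.05,"
            "Sr_ci_S002_c2_OG6_000003:0.01):0.05,Sr_ci_S003_c3_OG6_000003:0.01):0.2,"
            "(Sr_ci_S010_c4_OG6_000003:0.2,Sr_ci_S011_c5_OG6_000003:0.2):0.2):0.1,"
            "(Za_eu_S001_c6_OG6_000003:0.1,Za_eu_S002_c7_OG6_000003:0.1):0.3);"
        )
        rules = [
            SisterRule(f"r{i}", f"Sr_ci_S00{i}", ("Ba",), "any") for i in (1, 2, 3)
        ]
        result = run_loop({"OG6_000003": t}, [Phase("sisters", rules, 10)])
        removed = {r.seq_id for r in result.ledger.rows}
        assert removed == {
            "Sr_ci_S001_c1_OG6_000003", "Sr_ci_S002_c2_OG6_000003",
            "Sr_ci_S003_c3_OG6_000003",
        }
        iters = sorted({r.iteration for r in result.ledger.rows})
        assert iters == [1, 2, 3]  # one exposure per iteration

    def test_empty_rules_is_identity(self, rng):
        trees = {f"OG6_{i:06d}": random_gene_tree(rng) for i in range(3)}
        result = run_loop(trees, [Phase("sisters", [], 5)])
        assert len(result.ledger) == 0
        for gf, t in trees.items():
            assert sorted(result.kept[gf]) == sorted(t.leaf_labels())

    def test_conservation_and_ledger_bijection(self, rng):
        trees = {f"OG6_{i:06d}": random_gene_tree(rng) for i in range(5)}
        phases = [
            Phase("sisters", [SisterRule("r", "Op_me", ("Ba",), "any")], 5),
            Phase("clades", [CladeRule("c", "Sr_ci", 2, 0)], 2),
        ]
        result = run_loop(trees, phases)
        for gf, t in trees.items():
            inputs = set(t.leaf_labels())
            kept = set(result.kept[gf])
            removed = result.ledger.removed_ids(gf)
            assert kept | removed == inputs
            assert kept & removed == set()
        keys = [(r.gf, r.seq_id) for r in result.ledger.rows]
        assert len(keys) == len(set(keys))

    def test_converged_phase_is_idempotent(self, rng):
        trees = {f"OG6_{i:06d}": random_gene_tree(rng) for i in range(4)}
        phase = Phase("sisters", [SisterRule("r", "Op_me", ("Ba",), "any")], 10)
        first = run_loop(trees, [phase])
        again = run_loop(first.trees, [phase])
        assert len(again.ledger) == 0

    def test_phase_schedule_order_respected(self, rng):
        trees = {"OG6_000010": random_gene_tree(rng)}
        phases = [
            Phase("sisters", [SisterRule("r", "Op_me", ("Ba",), "any")], 10),
            Phase("subsisters", [SubsisterRule("s", ("Op_me_S000", "Op_me_S001"),
                                               ("non-Op",))], 5),
            Phase("clades", [CladeRule("c", "Sr_ci", 2, 0)], 2),
        ]
        result = run_loop(trees, phases)
        modes = [r.mode for r in result.ledger.rows]
        order = {"sister": 0, "subsister": 1, "clade": 2}
        assert modes == sorted(modes, key=order.__getitem__)


class TestRulesFiles:
    def test_sister_rules_round_trip(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text(
            "rule_id\tmode\ttarget\tforbidden\tbranch_mode\tmultiplier\n"
            "# a comment line\n"
            "r1\tsister\tSr_ci_Fehr\tEE_ha\tany\t0.5\n"
            "r2\tsister\tEE_ha\tBa,Za\tshort\t0.5\n"
            "ss1\tsubsister\tOp_ap_Ains;Op_ap_Atri\tnon-Op\t\t\n"
        )
        sisters, subsisters = read_sister_rules(path)
        assert [r.rule_id for r in sisters] == ["r1", "r2"]
        assert sisters[1].forbidden_sisters == ("Ba", "Za")
        assert sisters[1].branch_mode == "short"
        assert subsisters[0].pair == ("Op_ap_Ains", "Op_ap_Atri")

    def test_clade_rules_with_percent_allowance_and_exceptions(self, tmp_path):
        exc = tmp_path / "orphans.txt"
        exc.write_text("EE_he\n")
        path = tmp_path / "clades.tsv"
        path.write_text(
            "rule_id\ttarget\tmin_target\tallowance\texceptions_file\n"
            "c1\tOp_me\t11\t10%\torphans.txt\n"
            "c2\tSr_ci\t12\t0\t-\n"
        )
        rules = read_clade_rules(path)
        assert rules[0].nontarget_allowance == pytest.approx(0.10)
        assert rules[0].exceptions == ("EE_he",)
        assert rules[1].nontarget_allowance == 0

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text("r1\tsister\tSr_ci\tEE_ha\tany\t0.5\n")
        with pytest.raises(RuleError):
            read_sister_rules(path)
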