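import numpy as np
import pytest

import _oracles as oracle
from conftest import random_gene_tree
from phylocurate.tree_engine import (
    GeneTree,
    TreeError,
    avg_node_to_tip,
    cherry_partner,
    enumerate_clades,
    is_monophyletic,
    read_newick,
    root_tree,
    sister_group,
    write_newick,
)


def _gt(newick: str) -> GeneTree:
    return GeneTree.from_newick_string(newick)


class TestIO:
    def test_round_trip_preserves_bipartitions_and_lengths(self, tmp_path, rng):
        trees = [random_gene_tree(rng) for _ in range(5)]
        path = tmp_path / "trees.nwk"
        write_newick(trees, path)
        back = read_newick(path)
        assert len(back) == 5
        for a, b in zip(trees, back):
            assert oracle.all_below_sets(a).sort() == oracle.all_below_sets(b).sort()
            la = sorted((lf.taxon.label, round(lf.edge.length, 6))
                        for lf in a.tree.leaf_node_iter())
            lb = sorted((lf.taxon.label, round(lf.edge.length, 6))
                        for lf in b.tree.leaf_node_iter())
            assert la == lb

    def test_duplicate_leaf_label_rejected(self):
        with pytest.raises(TreeError):
            _gt("((Op_me_S001_c1_OG6_000001,Op_me_S001_c1_OG6_000001),"
                "Ba_pr_S003_c1_OG6_000001);")

    def test_invalid_leaf_label_rejected(self):
        with pytest.raises(Exception, match="not_a_seq_id"):
            _gt("((not_a_seq_id,Op_me_S001_c1_OG6_000001),Ba_pr_S003_c1_OG6_000001);")

    def test_lengths_absent_flagged_and_zero(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,Op_me_S002_c1_OG6_000001),"
                "Ba_pr_S003_c1_OG6_000001);")
        assert t.lengths_present is False
        assert avg_node_to_tip(t) == 0.0


class TestRooting:
    def test_outgroup_rooting_on_prokaryote_clade(self):
        t = _gt("((Ba_pr_S001_c1_OG6_000001:0.1,Ba_pr_S002_c1_OG6_000001:0.1):0.2,"
                "(Op_me_S003_c1_OG6_000001:0.1,Sr_ci_S004_c1_OG6_000001:0.1):0.2);")
        r = root_tree(t)
        sides = [
            {lf.taxon.label[:2] for lf in c.leaf_iter()}
            for c in r.tree.seed_node.child_nodes()
        ]
        assert {"Ba"} in sides

    def test_outgroup_found_across_input_root(self):
        # prokaryotes "wrap around" the arbitrary input rooting
        t = _gt("((Ba_pr_S001_c1_OG6_000001:0.1,(Op_me_S003_c1_OG6_000001:0.1,"
                "Op_me_S004_c1_OG6_000001:0.1):0.3):0.1,Za_eu_S002_c1_OG6_000001:0.1);")
        r = root_tree(t)
        sides = [
            frozenset(lf.taxon.label[:2] for lf in c.leaf_iter())
            for c in r.tree.seed_node.child_nodes()
        ]
        assert frozenset({"Op"}) in sides  # eukaryotes together, prokaryotes together

    def test_midpoint_fallback_for_all_eukaryote_tree(self):
        t = _gt("((Op_me_S003_c1_OG6_000001:0.1,Op_fu_S005_c1_OG6_000001:0.5):0.2,"
                "Sr_ci_S004_c1_OG6_000001:0.1);")
        r = root_tree(t)
        assert sorted(r.leaf_labels()) == sorted(t.leaf_labels())

    def test_too_few_leaves(self):
        t = _gt("(Op_me_S003_c1_OG6_000001:0.1,Sr_ci_S004_c1_OG6_000001:0.1);")
        with pytest.raises(TreeError):
            root_tree(t)


class TestBranchStats:
    def test_symmetric_cherry(self):
        t = _gt("(Op_me_S001_c1_OG6_000001:1.0,Op_me_S002_c1_OG6_000001:1.0);")
        assert avg_node_to_tip(t) == pytest.approx(1.0)

    def test_mean_terminal_branch(self):
        t = _gt("((Op_me_S001_c1_OG6_000001:0.1,Op_me_S002_c1_OG6_000001:0.2):0.5,"
                "Ba_pr_S003_c1_OG6_000001:0.3);")
        assert avg_node_to_tip(t) == pytest.approx(0.2)

    def test_root_to_tip_mode(self):
        t = _gt("((Op_me_S001_c1_OG6_000001:0.1,Op_me_S002_c1_OG6_000001:0.2):0.5,"
                "Ba_pr_S003_c1_OG6_000001:0.3);")
        assert avg_node_to_tip(t, mode="root_to_tip") == pytest.approx(
            (0.6 + 0.7 + 0.3) / 3
        )


class TestSisterGroups:
    def test_cherry_sister(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,Op_me_S002_c1_OG6_000001),"
                "Ba_pr_S003_c1_OG6_000001);")
        assert sister_group(t, "Op_me_S001_c1_OG6_000001") == {
            "Op_me_S002_c1_OG6_000001"
        }

    def test_multifurcation_pools_siblings(self):
        t = _gt("(Op_me_S001_c1_OG6_000001,Op_me_S002_c1_OG6_000001,"
                "Ba_pr_S003_c1_OG6_000001);")
        assert sister_group(t, "Op_me_S001_c1_OG6_000001") == {
            "Op_me_S002_c1_OG6_000001", "Ba_pr_S003_c1_OG6_000001"
        }

    def test_never_contains_query_and_cherry_symmetric(self, rng):
        for _ in range(20):
            t = random_gene_tree(rng)
            for lab in t.leaf_labels():
                sg = sister_group(t, lab)
                assert lab not in sg
                if len(sg) == 1:
                    partner = next(iter(sg))
                    if cherry_partner(t, lab) == partner:
                        assert cherry_partner(t, partner) == lab

    def test_missing_leaf(self):
        t = _gt("(Op_me_S001_c1_OG6_000001,Ba_pr_S003_c1_OG6_000001);")
        with pytest.raises(TreeError):
            sister_group(t, "Op_me_S999_c1_OG6_000001")


class TestCherryPartner:
    def test_examples(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,Op_me_S002_c1_OG6_000001),"
                "Ba_pr_S003_c1_OG6_000001);")
        assert cherry_partner(t, "Op_me_S001_c1_OG6_000001") == "Op_me_S002_c1_OG6_000001"
        assert cherry_partner(t, "Ba_pr_S003_c1_OG6_000001") is None

    def test_non_cherry_sibling_subtree(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,(Op_me_S002_c1_OG6_000001,"
                "Op_me_S003_c1_OG6_000001)),Ba_pr_S004_c1_OG6_000001);")
        assert cherry_partner(t, "Op_me_S001_c1_OG6_000001") is None


class TestEnumerateClades:
    def test_fractional_allowance_admits_one_interloper(self):
        labs = [f"Op_me_S{i:03d}_c{i}_OG6_000002:0.1" for i in range(12)]
        labs.append("Ex_pa_S099_c99_OG6_000002:0.1")
        t = _gt(f"(({','.join(labs)}):0.1,Ba_pr_S001_c0_OG6_000002:1.0);")
        hits = enumerate_clades(t, "Op_me", 0.10)
        assert len(hits) == 1
        assert (hits[0].target_count, hits[0].nontarget_count) == (12, 1)

    def test_pure_clade_zero_allowance(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,Op_me_S002_c2_OG6_000001),"
                "Ba_pr_S003_c3_OG6_000001);")
        hits = enumerate_clades(t, "Op_me", 0)
        assert len(hits) == 1 and hits[0].target_count == 2

    def test_counts_distinct_codes_not_sequences(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,Op_me_S001_c2_OG6_000001),"
                "Ba_pr_S003_c3_OG6_000001);")
        assert enumerate_clades(t, "Op_me", 0)[0].target_count == 1

    @pytest.mark.parametrize("bad", [-1, -0.5, 1.5])
    def test_malformed_allowance(self, bad):
        t = _gt("(Op_me_S001_c1_OG6_000001,Ba_pr_S003_c3_OG6_000001);")
        with pytest.raises(TreeError):
            enumerate_clades(t, "Op_me", bad)

    def test_matches_brute_force(self, rng):
        for _ in range(60):
            t = random_gene_tree(rng)
            for target in ("Op_me", "Op", "Sr_ci"):
                for allowance in (0, 1, 0.25):
                    got = {frozenset(h.leaf_labels)
                           for h in enumerate_clades(t, target, allowance)}
                    assert got == oracle.brute_enumerate_clades(t, target, allowance)


class TestIsMonophyletic:
    def test_clean_pair(self):
        t = _gt("((Op_me_S001_c1_OG6_000001,Op_me_S002_c1_OG6_000001),"
                "Ex_pa_S003_c1_OG6_000001);")
        assert is_monophyletic(t, "Op_me") is True

    def test_interloper_allowance_flips_status(self):
        t = _gt("(((Op_me_S001_c1_OG6_000001,Ex_pa_S005_c1_OG6_000001),"
                "Op_me_S002_c1_OG6_000001),(Ba_pr_S003_c1_OG6_000001,"
                "Ba_pr_S004_c1_OG6_000001));")
        assert is_monophyletic(t, "Op_me", 0) is False
        assert is_monophyletic(t, "Op_me", 1) is True

    def test_no_target_leaves_is_error(self):
        t = _gt("(Op_me_S001_c1_OG6_000001,Ex_pa_S003_c1_OG6_000001);")
        with pytest.raises(TreeError):
            is_monophyletic(t, "Pl_gr")

    def test_invariant_under_rerooting(self, rng):
        for _ in range(15):
            t = random_gene_tree(rng)
            expected = is_monophyletic(t, "Op_me") if any(
                l.startswith("Op_me") for l in t.leaf_labels()
            ) else None
            if expected is None:
                continue
            for node in list(t.tree.preorder_node_iter()):
                if node.parent_node is None:
                    continue
                clone = GeneTree.from_newick_string(t.as_newick(), validate=False)
                target_set = frozenset(lf.taxon.label for lf in node.leaf_iter())
                nd = next(
                    n for n in clone.tree.preorder_node_iter()
                    if frozenset(lf.taxon.label for lf in n.leaf_iter()) == target_set
                )
                clone.tree.reroot_at_edge(nd.edge)
                assert is_monophyletic(clone, "Op_me") == expected
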