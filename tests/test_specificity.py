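"""Clade propagation and SDP classification for the catalytic family."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from gutresp.model import AssignmentMethod, SpecificityAssignment
from gutresp.simulate import FamilySpec, generate_family_fixture
from gutresp.specificity import (
    FamilyTree,
    assign_specificities,
    classify_by_sdp,
    fit_sdp,
    propagate_by_clade,
    summarize_assignments,
)


def _tree(newick: str, known=None, contexts=None) -> FamilyTree:
    t = dendropy.Tree.get(data=f"[&R] {newick}", schema="newick")
    t.is_rooted = True
    return FamilyTree(
        tree=t,
        known=dict(known or {}),
        contexts={k: set(v) for k, v in (contexts or {}).items()},
    )


class TestPropagation:
    def test_shared_context_clade_propagates_known_label(self):
        ft = _tree(
            "((k1:1,u1:1):1,(k2:1,u2:1):1):0;",
            known={"k1": "nitrate", "k2": "nitrate"},
            contexts={t: {"ctx"} for t in ("k1", "u1", "k2", "u2")},
        )
        a = propagate_by_clade(ft)
        assert a["u1"].specificity == "nitrate"
        assert a["u2"].specificity == "nitrate"
        assert a["u1"].method is AssignmentMethod.PHYLOGENY
        assert a["k1"].method is AssignmentMethod.KNOWN

    def test_mixed_specificity_clade_propagates_nothing_inside(self):
        ft = _tree(
            "((nar:1,u1:1):1,(dms:1,u2:1):1):0;",
            known={"nar": "nitrate", "dms": "DMSO/TMAO"},
            contexts={t: {"ctx"} for t in ("nar", "u1", "dms", "u2")},
        )
        a = propagate_by_clade(ft)
        # the subclades still qualify individually
        assert a["u1"].specificity == "nitrate"
        assert a["u2"].specificity == "DMSO/TMAO"
        ft2 = _tree(
            "((nar:1,dms:1):1,u1:1):0;",
            known={"nar": "nitrate", "dms": "DMSO/TMAO"},
            contexts={t: {"ctx"} for t in ("nar", "dms", "u1")},
        )
        assert "u1" not in propagate_by_clade(ft2)

    def test_context_break_blocks_propagation(self):
        ft = _tree(
            "((k1:1,u1:1):1,k2:1):0;",
            known={"k1": "nitrate", "k2": "nitrate"},
            contexts={"k1": {"a"}, "u1": {"b"}, "k2": {"a"}},
        )
        assert "u1" not in propagate_by_clade(ft)

    def test_unrooted_tree_rejected_with_rooting_instruction(self):
        t = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick")
        t.is_rooted = False
        ft = FamilyTree(tree=t, known={"a": "nitrate"}, contexts={})
        with pytest.raises(ValueError, match="midpoint"):
            propagate_by_clade(ft)

    def test_idempotent_second_pass_assigns_nothing_new(self, family):
        first = propagate_by_clade(family.tree)
        second = propagate_by_clade(family.tree, existing=first)
        assert first == second

    def test_invariant_to_child_rotation(self, family):
        a1 = propagate_by_clade(family.tree)
        rotated = dendropy.Tree(family.tree.tree)
        for node in rotated.preorder_node_iter():
            node._child_nodes.reverse()
        ft = FamilyTree(
            tree=rotated, known=family.tree.known, contexts=family.tree.contexts
        )
        a2 = propagate_by_clade(ft)
        assert {
            (k, v.specificity, v.method) for k, v in a1.items()
        } == {(k, v.specificity, v.method) for k, v in a2.items()}

    def test_planted_clades_fully_recovered_without_noise(self):
        fx = generate_family_fixture(FamilySpec(seed=4, sdp_noise=0.0))
        a = propagate_by_clade(fx.tree)
        gt = fx.ground_truth["tip_group"]
        detached = set(fx.ground_truth["detached"])
        for tip, grp in gt.items():
            if tip in detached:
                assert tip not in a  # only the SDP route can reach these
            else:
                assert a[tip].specificity == grp


ALN = {
    "a1": "AAWW", "a2": "AAWW", "a3": "AAWW",
    "b1": "GGWW", "b2": "GGWW", "b3": "GGWW",
}
GROUPS = {s: s[0] for s in ALN}


class TestSDPFit:
    def test_perfectly_partitioning_column_selected_with_top_score(self):
        model = fit_sdp(ALN, GROUPS, n_permutations=200, seed=0)
        assert 0 in model.columns
        assert model.scores[0] == max(model.scores.values())
        # constant columns carry no discrimination
        assert 2 not in model.columns

    def test_gap_heavy_column_excluded_despite_signal(self):
        aln = {
            "a1": "A-", "a2": "A-", "a3": "AA", "a4": "A-", "a5": "AA",
            "b1": "GG", "b2": "GG", "b3": "GG", "b4": "GG", "b5": "GG",
        }
        groups = {s: s[0] for s in aln}
        model = fit_sdp(aln, groups, n_permutations=100, seed=0)
        assert 1 not in model.columns  # 60 % gaps in group a
        assert 0 in model.columns

    def test_uniform_columns_rarely_pass_the_null(self):
        """An i.i.d. uniform column should clear the z>=3 cutoff in well
        under 5 % of simulated alignments."""
        rng = np.random.default_rng(12)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        false_pos = 0
        n_sim = 200
        for k in range(n_sim):
            aln = {
                f"s{i}": "".join(
                    aas[rng.integers(0, 20)] for _ in range(3)
                )
                for i in range(10)
            }
            groups = {f"s{i}": "ab"[i % 2] for i in range(10)}
            model = fit_sdp(aln, groups, n_permutations=60, seed=k)
            false_pos += bool(model.columns)
        assert false_pos / n_sim <= 0.05

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ValueError, match=">=2 groups"):
            fit_sdp({"a1": "AA", "a2": "AA"}, {"a1": "a", "a2": "a"})


class TestSDPClassify:
    def test_consensus_match_assigns_group(self):
        model = fit_sdp(ALN, GROUPS, n_permutations=100, seed=0)
        assert classify_by_sdp(model, "AAWW") == "a"
        assert classify_by_sdp(model, "GGWW") == "b"

    def test_equidistant_sequence_stays_unknown(self):
        model = fit_sdp(ALN, GROUPS, n_permutations=100, seed=0)
        assert classify_by_sdp(model, "AGWW") is None

    def test_all_gap_at_sdp_columns_stays_unknown(self):
        model = fit_sdp(ALN, GROUPS, n_permutations=100, seed=0)
        gapped = "".join(
            "-" if c in model.columns else "A" for c in range(4)
        )
        assert classify_by_sdp(model, gapped) is None

    def test_planted_unknowns_recovered_at_stated_noise(self):
        fx = generate_family_fixture(FamilySpec(seed=9))
        a = assign_specificities(fx.tree, fx.alignment, seed=9)
        gt = fx.ground_truth["tip_group"]
        detached = fx.ground_truth["detached"]
        correct = sum(a[t].specificity == gt[t] for t in detached)
        assert correct / len(detached) >= 0.95
        for t in detached:
            if a[t].specificity != "unknown":
                assert a[t].method is AssignmentMethod.SDP


class TestSummaries:
    def test_counts_reproduce_a_calibrated_split(self):
        """Regression on the counting operation with a reference method
        split (40 known, 191 by phylogeny, 48 by SDP, 109 unassigned)."""
        assignments = {}
        i = 0
        for method, spec, count in [
            (AssignmentMethod.KNOWN, "nitrate", 40),
            (AssignmentMethod.PHYLOGENY, "nitrate", 191),
            (AssignmentMethod.SDP, "TMAO", 48),
            (AssignmentMethod.UNASSIGNED, "unknown", 109),
        ]:
            for _ in range(count):
                pid = f"P{i:04d}"
                assignments[pid] = SpecificityAssignment(pid, spec, method)
                i += 1
        out = summarize_assignments(assignments)
        assert out["counts"] == {
            "known": 40, "phylogeny": 191, "sdp": 48, "unassigned": 109,
        }
        assert len(out["unassigned"]) == 109

    def test_no_assignments_never_contradict_known_labels(self, family):
        a = assign_specificities(family.tree, family.alignment, seed=0)
        for tip, spec in family.tree.known.items():
            assert a[tip].specificity == spec
            assert a[tip].method is AssignmentMethod.KNOWN

    def test_all_known_tips_leave_other_methods_empty(self):
        ft = _tree(
            "((a:1,b:1):1,c:1):0;",
            known={"a": "x", "b": "x", "c": "x"},
            contexts={t: {"ctx"} for t in "abc"},
        )
        out = summarize_assignments(propagate_by_clade(ft))
        assert out["counts"]["phylogeny"] == 0
        assert out["counts"]["sdp"] == 0

    def test_no_known_tips_means_everything_unassigned(self):
        ft = _tree("((a:1,b:1):1,c:1):0;", known={}, contexts={})
        with pytest.raises(ValueError):
            propagate_by_clade(ft)
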