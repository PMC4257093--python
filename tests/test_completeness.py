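"""Completeness assessment: essential-gene diagnostic and length rule."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_genome
from gutresp.completeness import (
    RelatednessProvider,
    assess_completeness_by_length,
    essential_gene_fraction,
    find_related_finished,
)
from gutresp.model import Completeness, Genome, Registry, Status


def _registry_with_families(n_families: int, n_present: int) -> Registry:
    reg = Registry()
    genes = [
        (f"P{k}", 100 + 1000 * k, 900 + 1000 * k, "+", {f"ESS{k:04d}"}, False, 0)
        for k in range(n_present)
    ]
    make_genome(reg, "G1", genes)
    return reg


class TestEssentialFraction:
    def test_partial_presence(self):
        reg = _registry_with_families(1000, 849)
        fams = {f"ESS{k:04d}" for k in range(1000)}
        frac = essential_gene_fraction(reg.genomes["G1"], fams, reg)
        assert frac == pytest.approx(0.849)

    def test_all_and_none(self):
        reg = _registry_with_families(100, 100)
        fams = {f"ESS{k:04d}" for k in range(100)}
        assert essential_gene_fraction(reg.genomes["G1"], fams, reg) == 1.0
        other = {f"OTH{k:04d}" for k in range(50)}
        assert essential_gene_fraction(reg.genomes["G1"], other, reg) == 0.0

    def test_empty_family_set_is_an_error(self):
        reg = _registry_with_families(10, 10)
        with pytest.raises(ValueError):
            essential_gene_fraction(reg.genomes["G1"], set(), reg)

    def test_finished_genome_can_score_low(self, panel, result):
        """A finished genome holds the panel's lowest essential fraction,
        which is why the fraction never drives the verdict."""
        worst = panel.ground_truth["essential_worst"]
        gid = worst["genome"]
        assert panel.registry.genomes[gid].status is Status.FINISHED
        assert result.essential_fractions[gid] == pytest.approx(worst["fraction"])
        assert min(result.essential_fractions.values()) == pytest.approx(
            worst["fraction"]
        )


def _genome(gid, taxon, status, length):
    return Genome(id=gid, taxon=taxon, status=status, length_bp=length)


class TestRelatedFinished:
    def _registry(self):
        reg = Registry()
        reg.add_genome(_genome("F1", "Alpha one", Status.FINISHED, 3_200_000))
        reg.add_genome(_genome("F2", "Alpha one", Status.FINISHED, 3_900_000))
        reg.add_genome(_genome("F3", "Alpha two", Status.FINISHED, 2_500_000))
        reg.add_genome(_genome("F4", "Beta three", Status.FINISHED, 4_000_000))
        return reg

    def test_species_tier_preempts_genus(self):
        reg = self._registry()
        draft = _genome("D1", "Alpha one", Status.DRAFT, 3_400_000)
        reg.add_genome(draft)
        rel = find_related_finished(draft, reg)
        assert {g.id for g in rel} == {"F1", "F2"}

    def test_genus_tier(self):
        reg = self._registry()
        draft = _genome("D1", "Alpha novel", Status.DRAFT, 3_400_000)
        reg.add_genome(draft)
        assert {g.id for g in find_related_finished(draft, reg)} == {
            "F1", "F2", "F3",
        }

    def test_sixteen_s_tier_takes_maximal_identity(self):
        reg = self._registry()
        draft = _genome("D1", "Gamma other", Status.DRAFT, 3_400_000)
        reg.add_genome(draft)
        prov = RelatednessProvider()
        prov.set_identity("D1", "F1", 0.97)
        prov.set_identity("D1", "F3", 0.92)
        assert [g.id for g in find_related_finished(draft, reg, prov)] == ["F1"]

    def test_no_finished_genomes_yields_empty(self):
        reg = Registry()
        draft = _genome("D1", "Alpha one", Status.DRAFT, 3_400_000)
        reg.add_genome(draft)
        assert find_related_finished(draft, reg) == []

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RelatednessProvider().set_identity("A", "B", 1.2)


class TestLengthRule:
    F = [
        _genome("F1", "Alpha one", Status.FINISHED, 3_200_000),
        _genome("F2", "Alpha one", Status.FINISHED, 3_900_000),
    ]

    def test_longer_than_one_relative_is_probably_complete(self):
        d = _genome("D", "Alpha one", Status.DRAFT, 3_400_000)
        assert (
            assess_completeness_by_length(d, self.F)
            is Completeness.PROBABLY_COMPLETE
        )

    def test_shorter_than_all_relatives_is_incomplete(self):
        d = _genome("D", "Alpha one", Status.DRAFT, 2_800_000)
        assert assess_completeness_by_length(d, self.F) is Completeness.INCOMPLETE

    def test_tie_counts_as_complete(self):
        d = _genome("D", "Alpha one", Status.DRAFT, 3_200_000)
        assert (
            assess_completeness_by_length(d, self.F)
            is Completeness.PROBABLY_COMPLETE
        )

    def test_finished_genome_bypasses_comparison(self):
        f = _genome("F", "Alpha one", Status.FINISHED, 1_000_000)
        assert assess_completeness_by_length(f, []) is Completeness.COMPLETE

    def test_no_relatives_is_unassessable(self):
        d = _genome("D", "Alpha one", Status.DRAFT, 3_400_000)
        assert assess_completeness_by_length(d, []) is Completeness.UNASSESSABLE

    def test_monotone_in_draft_length_and_relative_set(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            lengths = rng.integers(1_000_000, 5_000_000, size=3)
            rel = [
                _genome(f"F{i}", "A b", Status.FINISHED, int(l))
                for i, l in enumerate(lengths)
            ]
            d = _genome("D", "A b", Status.DRAFT, int(rng.integers(1_000_000, 5_000_000)))
            verdict = assess_completeness_by_length(d, rel)
            longer = _genome("D2", "A b", Status.DRAFT, d.length_bp + 100_000)
            if verdict is Completeness.PROBABLY_COMPLETE:
                assert (
                    assess_completeness_by_length(longer, rel)
                    is Completeness.PROBABLY_COMPLETE
                )
                shorter_rel = rel + [
                    _genome("F9", "A b", Status.FINISHED, max(1, d.length_bp - 1))
                ]
                assert (
                    assess_completeness_by_length(d, shorter_rel)
                    is Completeness.PROBABLY_COMPLETE
                )


class TestPanelAssessment:
    def test_partition_is_disjoint_and_total(self, result):
        counts = result.completeness_counts
        assert sum(counts.values()) == 254
        assert set(counts) <= {
            "complete", "probably_complete", "incomplete", "unassessable",
        }

    def test_calibrated_marginals(self, result):
        assert result.completeness_counts["complete"] == 55
        assert result.completeness_counts["probably_complete"] == 149
        assert result.completeness_counts["incomplete"] == 50

    def test_verdicts_match_planted_truth(self, panel, result):
        truth = panel.ground_truth["completeness"]
        for gid, expected in truth.items():
            assert panel.registry.genomes[gid].completeness.value == expected
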