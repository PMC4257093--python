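"""BBH orthology, context confirmation and reductase presence calls."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_genome
from gutresp.model import Registry
from gutresp.orthologs import (
    OrthologPair,
    SimilarityTable,
    all_bbh_pairs,
    best_bidirectional_hits,
    call_reductases,
    confirm_all,
    confirm_context,
)


def _two_genome_registry(n_a=5, n_b=5):
    reg = Registry()
    make_genome(
        reg, "A",
        [(f"A{i}", 100 + 1000 * i, 900 + 1000 * i, "+", set(), False, 0)
         for i in range(n_a)],
    )
    make_genome(
        reg, "B",
        [(f"B{i}", 100 + 1000 * i, 900 + 1000 * i, "+", set(), False, 0)
         for i in range(n_b)],
    )
    return reg


def _brute_force_bbh(rows, reg, ga, gb, cutoff):
    """Independent oracle: direct double loop over all protein pairs."""
    a_prots = sorted(p.id for p in reg.proteins_of_genome(ga))
    b_prots = sorted(p.id for p in reg.proteins_of_genome(gb))
    score = {}
    for q, s, bits, ev in rows:
        key = (q, s)
        if key not in score or bits > score[key][0]:
            score[key] = (bits, ev)

    def best(q, subjects):
        cands = [
            (s, score[(q, s)]) for s in subjects if (q, s) in score
        ]
        if not cands:
            return None
        top = max(b for _, (b, _) in cands)
        return sorted(s for s, (b, _) in cands if b == top)[0]

    pairs = set()
    for a in a_prots:
        b = best(a, b_prots)
        if b is None:
            continue
        if best(b, a_prots) != a:
            continue
        if score[(a, b)][1] <= cutoff and score[(b, a)][1] <= cutoff:
            pairs.add(frozenset((a, b)))
    return pairs


class TestBBH:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            reg = _two_genome_registry(6, 6)
            rows = []
            for a, b in itertools.product(range(6), range(6)):
                if rng.random() < 0.5:
                    bits = float(rng.integers(100, 600))
                    rows.append((f"A{a}", f"B{b}", bits, 10.0 ** (-bits / 10)))
                if rng.random() < 0.5:
                    bits = float(rng.integers(100, 600))
                    rows.append((f"B{b}", f"A{a}", bits, 10.0 ** (-bits / 10)))
            sim = SimilarityTable.from_records(rows)
            got = {
                p.members
                for p in best_bidirectional_hits(sim, reg, "A", "B", 1e-20)
            }
            assert got == _brute_force_bbh(rows, reg, "A", "B", 1e-20)

    def test_planted_orthologs_with_lower_noise_recovered_exactly(self):
        reg = _two_genome_registry(4, 4)
        rows = []
        for i in range(4):
            rows.append((f"A{i}", f"B{i}", 500.0, 1e-50))
            rows.append((f"B{i}", f"A{i}", 500.0, 1e-50))
            # noise hits 10 bits lower
            j = (i + 1) % 4
            rows.append((f"A{i}", f"B{j}", 490.0, 1e-49))
            rows.append((f"B{j}", f"A{i}", 490.0, 1e-49))
        sim = SimilarityTable.from_records(rows)
        pairs = best_bidirectional_hits(sim, reg, "A", "B", 1e-20)
        assert {p.members for p in pairs} == {
            frozenset((f"A{i}", f"B{i}")) for i in range(4)
        }

    def test_non_reciprocal_best_forms_no_pair(self):
        reg = _two_genome_registry(2, 2)
        rows = [
            ("A0", "B0", 500.0, 1e-50),
            ("B0", "A1", 500.0, 1e-50),  # B0 prefers A1
            ("A1", "B1", 400.0, 1e-40),
            ("B1", "A1", 500.0, 1e-50),
        ]
        sim = SimilarityTable.from_records(rows)
        pairs = best_bidirectional_hits(sim, reg, "A", "B", 1e-20)
        assert all("A0" not in p.members for p in pairs)

    def test_ties_resolve_to_lexicographically_smallest_subject(self):
        reg = _two_genome_registry(1, 2)
        rows = [
            ("A0", "B0", 500.0, 1e-50),
            ("A0", "B1", 500.0, 1e-50),
            ("B0", "A0", 500.0, 1e-50),
            ("B1", "A0", 500.0, 1e-50),
        ]
        sim = SimilarityTable.from_records(rows)
        pairs = best_bidirectional_hits(sim, reg, "A", "B", 1e-20)
        assert {p.members for p in pairs} == {frozenset(("A0", "B0"))}

    def test_symmetric_in_genome_arguments(self):
        rng = np.random.default_rng(3)
        reg = _two_genome_registry(5, 5)
        rows = []
        for a, b in itertools.product(range(5), range(5)):
            bits = float(rng.integers(150, 600))
            rows.append((f"A{a}", f"B{b}", bits, 10.0 ** (-bits / 10)))
            bits = float(rng.integers(150, 600))
            rows.append((f"B{b}", f"A{a}", bits, 10.0 ** (-bits / 10)))
        sim = SimilarityTable.from_records(rows)
        ab = {p.members for p in best_bidirectional_hits(sim, reg, "A", "B")}
        ba = {p.members for p in best_bidirectional_hits(sim, reg, "B", "A")}
        assert ab == ba

    def test_cutoff_excludes_weak_pairs(self):
        reg = _two_genome_registry(1, 1)
        rows = [("A0", "B0", 150.0, 1e-15), ("B0", "A0", 150.0, 1e-15)]
        sim = SimilarityTable.from_records(rows)
        assert not best_bidirectional_hits(sim, reg, "A", "B", 1e-20)
        assert best_bidirectional_hits(sim, reg, "A", "B", 1e-10)


class TestContext:
    def test_syntenic_block_confirms_every_pair(self):
        reg = _two_genome_registry(3, 3)
        pairs = {OrthologPair(f"A{i}", f"B{i}") for i in range(3)}
        for p in pairs:
            assert confirm_context(p, reg, pairs, window_k=5)

    def test_isolated_pair_with_shuffled_neighbourhood_unconfirmed(self):
        reg = _two_genome_registry(3, 3)
        pairs = {OrthologPair("A0", "B0")}
        assert not confirm_context(OrthologPair("A0", "B0"), reg, pairs, 5)

    def test_gene_alone_on_contig_unconfirmed(self):
        reg = Registry()
        make_genome(reg, "A", [("A0", 100, 900, "+", set(), False, 0)])
        make_genome(
            reg, "B",
            [(f"B{i}", 100 + 1000 * i, 900 + 1000 * i, "+", set(), False, 0)
             for i in range(3)],
        )
        pairs = {OrthologPair("A0", "B0"), OrthologPair("A1", "B1")}
        assert not confirm_context(OrthologPair("A0", "B0"), reg, pairs, 5)

    def test_confirm_all_agrees_with_pairwise_confirmation(self, small_panel):
        reg = small_panel.registry
        ref = small_panel.ground_truth["reference_genome"]
        gids = [g for g in sorted(reg.genomes) if g != ref]
        pairs = all_bbh_pairs(
            small_panel.similarity, reg, [(g, ref) for g in gids]
        )
        confirmed = {p.members for p in confirm_all(pairs, reg, 5)}
        expected = {
            p.members for p in pairs if confirm_context(p, reg, pairs, 5)
        }
        assert confirmed == expected


class TestCalls:
    def test_presence_matrix_matches_planted_truth(self, panel, result):
        truth = panel.ground_truth["reductases"]
        m = result.matrix
        for gid, expected in truth.items():
            called = {c: int(m.at[gid, c]) for c in m.columns if m.at[gid, c]}
            assert called == expected, gid

    def test_multi_copy_reductase_counted_as_copy_number(self, panel, result):
        multi = panel.ground_truth["lego"]["multi_copy_dms"]
        for gid, copies in multi.items():
            assert int(result.matrix.at[gid, "Dms"]) == copies
        # presence-for-classification collapses copies to one
        row = result.calls.presence_row(list(multi)[0])
        assert row["Dms"] == 12 and result.calls.presence(list(multi)[0], "Dms")

    def test_genome_without_orthologs_has_empty_row(self, panel, result):
        zeros = [
            g
            for g, red in panel.ground_truth["reductases"].items()
            if not red
        ]
        assert zeros
        for gid in zeros[:5]:
            assert int(result.matrix.loc[gid].sum()) == 0

    def test_presence_invariant_to_similarity_row_order(self, small_panel):
        reg = small_panel.registry
        ref = small_panel.ground_truth["reference_genome"]
        gids = [g for g in sorted(reg.genomes) if g != ref]
        shuffled = SimilarityTable(
            small_panel.similarity.frame.sample(frac=1.0, random_state=11)
        )
        m1 = call_reductases(
            reg,
            confirm_all(
                all_bbh_pairs(small_panel.similarity, reg, [(g, ref) for g in gids]),
                reg,
            ),
            similarity=small_panel.similarity,
        ).matrix
        m2 = call_reductases(
            reg,
            confirm_all(
                all_bbh_pairs(shuffled, reg, [(g, ref) for g in gids]), reg
            ),
            similarity=shuffled,
        ).matrix
        pd.testing.assert_frame_equal(m1, m2)
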