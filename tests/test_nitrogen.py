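"""Nitrogen-oxide profiles, route completeness and exchange inference."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gutresp.catalog import default_catalog
from gutresp.model import (
    ExchangeEdge,
    NITROGEN_STEPS,
    OxygenClass,
    OxygenClassValue,
    PathwayProfile,
)
from gutresp.nitrogen import (
    DEFAULT_ANAEROBIC_SET,
    DEFAULT_MICROAEROBIC_SET,
    METABOLITE_STEPS,
    classify_pathway,
    infer_exchange_network,
    pathway_profile,
)

CAT = default_catalog()
MICRO = OxygenClass(OxygenClassValue.MICROAEROPHILIC)
ANA = OxygenClass(OxygenClassValue.ANAEROBIC)


def _row(**kw):
    row = {name: 0 for name in CAT}
    row.update(kw)
    return row


def _profile(genome_id, steps, transporters=frozenset()):
    p = PathwayProfile(genome_id=genome_id)
    for step, enzymes in steps.items():
        p.steps[step] = set(enzymes)
    p.transporters = set(transporters)
    return p


class TestProfiles:
    def test_nitrate_reducer_with_antiporter(self):
        p = pathway_profile("G", _row(Nar=1, NarK=1), CAT)
        assert p.has_step("NO3->NO2", "respiratory")
        assert p.transporters == {"NarK"}
        assert not any(
            p.has_step(s) for s in NITROGEN_STEPS if s != "NO3->NO2"
        )

    def test_nitrite_only_reducer(self):
        p = pathway_profile("G", _row(Nrf=1), CAT)
        assert p.has_step("NO2->NH3", "respiratory")
        assert not p.has_step("NO3->NO2")

    def test_empty_presence_gives_empty_profile(self):
        assert pathway_profile("G", _row(), CAT).empty

    def test_assimilatory_enzymes_carry_their_mode_tag(self):
        p = pathway_profile("G", _row(NirBD=1), CAT)
        assert p.has_step("NO2->NH3", "assimilatory")
        assert not p.has_step("NO2->NH3", "respiratory")


class TestRouteCompleteness:
    def test_nitrate_plus_nitrite_to_ammonia_is_complete(self):
        p = pathway_profile("G", _row(Nar=1, Nrf=1), CAT)
        cls, missing = classify_pathway(p)
        assert cls == "complete_ammonification"
        assert missing["ammonification"] == []

    def test_full_denitrification_chain(self):
        p = pathway_profile("G", _row(Nar=1, Nir=1, Nor=1, Nos=1), CAT)
        assert classify_pathway(p)[0] == "complete_denitrification"

    def test_skipped_intermediate_step_is_partial(self):
        """Nitrate and nitric-oxide reduction without the nitrite-to-NO
        step in between."""
        p = pathway_profile("G", _row(Nar=1, Nor=1), CAT)
        cls, missing = classify_pathway(p)
        assert cls == "partial"
        assert "NO2->NO" in missing["denitrification"]

    def test_no_steps_is_none(self):
        assert classify_pathway(pathway_profile("G", _row(), CAT))[0] == "none"

    def test_assimilatory_enzyme_does_not_complete_a_route(self):
        p = pathway_profile("G", _row(Nar=1, NirBD=1), CAT)
        assert classify_pathway(p)[0] == "partial"

    def test_calibrated_route_counts(self, result):
        counts = result.pathway["counts"]
        assert counts["complete_ammonification"] == 28
        assert counts["complete_denitrification"] == 1
        assert counts["partial"] == 44
        assert counts["with_any_pathway"] == 73


def _brute_force_edges(profiles, classes, include_n2o=False):
    """Independent oracle: literal enumeration of the edge rule."""
    mets = ["nitrite", "nitric_oxide"] + (["nitrous_oxide"] if include_n2o else [])
    edges = set()
    for met in mets:
        prod_step, cons_steps = METABOLITE_STEPS[met]
        for p, c in itertools.permutations(profiles, 2):
            pp, pc = profiles[p], profiles[c]
            if not pp.has_step(prod_step, "respiratory"):
                continue
            if any(pp.has_step(s) for s in cons_steps):
                continue
            if not any(pc.has_step(s, "respiratory") for s in cons_steps):
                continue
            if pc.has_step(prod_step, "respiratory"):
                continue
            a, b = classes[p].value, classes[c].value
            micro = DEFAULT_MICROAEROBIC_SET
            ana = DEFAULT_ANAEROBIC_SET
            if (a in micro and b in micro) or (a in ana and b in ana):
                edges.add(ExchangeEdge(p, met, c))
    return edges


class TestExchange:
    def test_nitrate_reducer_feeds_nitrite_respiring_neighbour(self):
        profiles = {
            "L": pathway_profile("L", _row(Nar=1, NarK=1), CAT),
            "B": pathway_profile("B", _row(Nrf=1), CAT),
        }
        classes = {"L": MICRO, "B": MICRO}
        edges = infer_exchange_network(profiles, classes)
        assert edges == {ExchangeEdge("L", "nitrite", "B")}

    def test_nitric_oxide_handoff(self):
        profiles = {
            "A": pathway_profile("A", _row(Nar=1, Nir=1), CAT),
            "V": pathway_profile("V", _row(Nar=1, Nor=1), CAT),
        }
        classes = {"A": MICRO, "V": MICRO}
        edges = infer_exchange_network(profiles, classes)
        assert ExchangeEdge("A", "nitric_oxide", "V") in edges
        # A consumes its own nitrite, so it is no nitrite producer
        assert not any(
            e.metabolite == "nitrite" and e.producer == "A" for e in edges
        )

    def test_complete_pathway_community_has_no_edges(self):
        profiles = {
            g: pathway_profile(g, _row(Nar=1, Nrf=1), CAT) for g in "XYZ"
        }
        classes = {g: ANA for g in "XYZ"}
        assert infer_exchange_network(profiles, classes) == set()

    def test_assimilatory_consumer_is_excluded_as_producer_but_not_served(self):
        profiles = {
            "P": pathway_profile("P", _row(Nar=1, NirBD=1), CAT),
            "C": pathway_profile("C", _row(Nrf=1), CAT),
        }
        classes = {"P": MICRO, "C": MICRO}
        edges = infer_exchange_network(profiles, classes)
        # P consumes nitrite assimilatorily: not a producer...
        assert not any(e.producer == "P" for e in edges)
        # ...and an assimilatory enzyme never makes a network consumer
        assert not any(e.consumer == "P" for e in edges)

    def test_cohabitation_gate_blocks_cross_zone_pairs(self):
        profiles = {
            "L": pathway_profile("L", _row(Nar=1), CAT),
            "B": pathway_profile("B", _row(Nrf=1), CAT),
        }
        classes = {"L": MICRO, "B": ANA}
        assert infer_exchange_network(profiles, classes) == set()

    def test_mismatched_genome_sets_error(self):
        profiles = {"A": pathway_profile("A", _row(), CAT)}
        with pytest.raises(ValueError):
            infer_exchange_network(profiles, {"B": ANA})

    def test_n2o_edges_only_behind_the_flag(self):
        profiles = {
            "V": pathway_profile("V", _row(Nor=1), CAT),
            "R": pathway_profile("R", _row(Nos=1), CAT),
        }
        classes = {"V": ANA, "R": ANA}
        assert infer_exchange_network(profiles, classes) == set()
        with_n2o = infer_exchange_network(profiles, classes, include_n2o=True)
        assert with_n2o == {ExchangeEdge("V", "nitrous_oxide", "R")}

    def test_matches_brute_force_on_random_profile_sets(self):
        rng = np.random.default_rng(5)
        enzymes = ["Nar", "Nap", "Nrf", "Nir", "Nor", "Nos", "NirBD", "NasBA"]
        for _ in range(40):
            profiles, classes = {}, {}
            for g in range(int(rng.integers(2, 8))):
                gid = f"G{g}"
                row = _row(**{e: int(rng.random() < 0.4) for e in enzymes})
                profiles[gid] = pathway_profile(gid, row, CAT)
                classes[gid] = rng.choice([MICRO, ANA])
            got = infer_exchange_network(profiles, classes)
            assert got == _brute_force_edges(profiles, classes)

    def test_removing_a_genome_never_creates_edges(self, result):
        full = result.edges
        profiles = dict(result.profiles)
        classes = {g: result.classes[g] for g in profiles}
        victims = list(profiles)[:: max(1, len(profiles) // 5)][:5]
        for victim in victims:
            sub_p = {g: p for g, p in profiles.items() if g != victim}
            sub_c = {g: c for g, c in classes.items() if g != victim}
            sub = infer_exchange_network(sub_p, sub_c)
            survivors = {
                e for e in full if victim not in (e.producer, e.consumer)
            }
            assert sub == survivors

    def test_planted_producers_and_consumers_are_wired(self, panel, result):
        gt = panel.ground_truth["nitrogen"]
        producers = {e.producer for e in result.edges if e.metabolite == "nitrite"}
        consumers = {e.consumer for e in result.edges if e.metabolite == "nitrite"}
        assert set(gt["producer_only_nitrite"]) <= producers
        assert set(gt["consumer_only_nitrite"]) <= consumers
        no_prod = {
            e.producer for e in result.edges if e.metabolite == "nitric_oxide"
        }
        no_cons = {
            e.consumer for e in result.edges if e.metabolite == "nitric_oxide"
        }
        assert set(gt["producer_nitric_oxide"]) <= no_prod
        assert set(gt["consumer_nitric_oxide"]) <= no_cons
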