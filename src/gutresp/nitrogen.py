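"""Nitrogen-oxide pathway profiling and exchange-network inference.

Respiratory nitrate reduction proceeds NO3 -> NO2 -> {NH3 | NO -> N2O ->
N2}; many gut genomes carry only fragments of either route.  Fragments
complement each other across genomes, so organisms sharing a habitat
zone can hand intermediates over: one reduces nitrate to nitrite,
another respires the nitrite.  This module builds per-genome step
profiles from the presence matrix, classifies route completeness, and
infers producer -> consumer exchange edges for nitrite and nitric oxide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .model import (
    ExchangeEdge,
    NITROGEN_STEPS,
    OxygenClass,
    OxygenClassValue,
    PathwayProfile,
    ReductaseCatalogEntry,
)

AMMONIFICATION_STEPS = ("NO3->NO2", "NO2->NH3")
DENITRIFICATION_STEPS = ("NO3->NO2", "NO2->NO", "NO->N2O", "N2O->N2")

# Step producing / consuming each exchangeable intermediate.
METABOLITE_STEPS: Dict[str, Tuple[str, Tuple[str, ...]]] = {
    "nitrite": ("NO3->NO2", ("NO2->NH3", "NO2->NO")),
    "nitric_oxide": ("NO2->NO", ("NO->N2O",)),
    "nitrous_oxide": ("NO->N2O", ("N2O->N2",)),
}

# Genomes eligible to co-habit the same intestinal zone: both partners
# microaerobic-capable, or both anaerobic.
DEFAULT_MICROAEROBIC_SET = frozenset(
    {
        OxygenClassValue.MICROAEROPHILIC,
        OxygenClassValue.AT_LEAST_MICROAEROPHILIC,
    }
)
DEFAULT_ANAEROBIC_SET = frozenset(
    {OxygenClassValue.ANAEROBIC, OxygenClassValue.MOST_LIKELY_ANAEROBIC}
)


def pathway_profile(
    genome_id: str,
    presence_row: Mapping[str, int],
    catalog: Mapping[str, ReductaseCatalogEntry],
) -> PathwayProfile:
    """Per-step enzyme sets (with respiratory/assimilatory mode tags) and
    transporters, from one genome's presence row."""
    profile = PathwayProfile(genome_id=genome_id)
    for name, copies in presence_row.items():
        if copies <= 0 or name not in catalog:
            continue
        entry = catalog[name]
        if entry.pathway_step is None:
            continue
        if entry.pathway_step == "transporter":
            profile.transporters.add(name)
        else:
            profile.steps[entry.pathway_step].add((name, entry.mode))
    return profile


def classify_pathway(
    profile: PathwayProfile,
) -> Tuple[str, Dict[str, List[str]]]:
    """Route completeness over respiratory steps.

    Returns (classification, missing) where classification is one of
    complete_ammonification / complete_denitrification / partial / none
    and missing maps each route to its absent steps.  Assimilatory
    enzymes do not complete a respiratory route.
    """
    has = {step: profile.has_step(step, "respiratory") for step in NITROGEN_STEPS}
    missing = {
        "ammonification": [s for s in AMMONIFICATION_STEPS if not has[s]],
        "denitrification": [s for s in DENITRIFICATION_STEPS if not has[s]],
    }
    if not missing["denitrification"]:
        return "complete_denitrification", missing
    if not missing["ammonification"]:
        return "complete_ammonification", missing
    if any(has.values()):
        return "partial", missing
    return "none", missing


def _cohabitation_eligible(
    a: OxygenClass,
    b: OxygenClass,
    microaerobic_set: frozenset,
    anaerobic_set: frozenset,
) -> bool:
    return (a.value in microaerobic_set and b.value in microaerobic_set) or (
        a.value in anaerobic_set and b.value in anaerobic_set
    )


def infer_exchange_network(
    profiles: Mapping[str, PathwayProfile],
    oxygen_classes: Mapping[str, OxygenClass],
    microaerobic_set: frozenset = DEFAULT_MICROAEROBIC_SET,
    anaerobic_set: frozenset = DEFAULT_ANAEROBIC_SET,
    include_n2o: bool = False,
) -> Set[ExchangeEdge]:
    """Exchange edges (producer, metabolite, consumer).

    A producer performs the respiratory step generating the metabolite
    and cannot consume it by any route (respiratory or assimilatory); a
    consumer performs a respiratory consuming step and cannot produce the
    metabolite respiratorily.  Assimilatory enzymes therefore exclude a
    genome from needing imports but never make it a producer.  Both ends
    must be co-habitation eligible (same oxygen zone).
    """
    if set(profiles) != set(oxygen_classes):
        raise ValueError("profiles and oxygen classes cover different genomes")
    metabolites = ["nitrite", "nitric_oxide"] + (
        ["nitrous_oxide"] if include_n2o else []
    )
    edges: Set[ExchangeEdge] = set()
    for metabolite in metabolites:
        prod_step, cons_steps = METABOLITE_STEPS[metabolite]
        producers = [
            g
            for g, p in profiles.items()
            if p.has_step(prod_step, "respiratory")
            and not any(p.has_step(s) for s in cons_steps)
        ]
        consumers = [
            g
            for g, p in profiles.items()
            if any(p.has_step(s, "respiratory") for s in cons_steps)
            and not p.has_step(prod_step, "respiratory")
        ]
        for producer in producers:
            for consumer in consumers:
                if producer == consumer:
                    continue
                if _cohabitation_eligible(
                    oxygen_classes[producer],
                    oxygen_classes[consumer],
                    microaerobic_set,
                    anaerobic_set,
                ):
                    edges.add(ExchangeEdge(producer, metabolite, consumer))
    return edges


def edges_to_frame(edges: Iterable[ExchangeEdge]) -> pd.DataFrame:
    rows = sorted(
        (e.producer, e.metabolite, e.consumer) for e in edges
    )
    return pd.DataFrame(rows, columns=["producer", "metabolite", "consumer"])


def edges_to_graph(edges: Iterable[ExchangeEdge]) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(e.producer, e.consumer, metabolite=e.metabolite)
    return g


def write_edges(edges: Iterable[ExchangeEdge], tsv_path=None, graphml_path=None):
    edges = list(edges)
    if tsv_path is not None:
        edges_to_frame(edges).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(edges_to_graph(edges), graphml_path)


def pathway_summary(
    profiles: Mapping[str, PathwayProfile],
) -> Dict[str, object]:
    """Counts of route-completeness classes over the profiled genomes."""
    counts = {
        "complete_ammonification": 0,
        "complete_denitrification": 0,
        "partial": 0,
        "none": 0,
    }
    per_genome: Dict[str, str] = {}
    for genome_id, profile in profiles.items():
        cls, _ = classify_pathway(profile)
        counts[cls] += 1
        per_genome[genome_id] = cls
    counts["with_any_pathway"] = (
        counts["complete_ammonification"]
        + counts["complete_denitrification"]
        + counts["partial"]
    )
    return {"counts": counts, "per_genome": per_genome}
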