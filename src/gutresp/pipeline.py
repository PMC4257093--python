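"""End-to-end orchestration of the respiratory-capacity analysis.

Runs the full chain on a panel (generated or loaded from a fixture
directory): completeness assessment, BBH reductase calls with context
confirmation, oxygen-lifestyle classification, label-consistency
scoring, nitrogen-oxide profiling with exchange-network inference, the
complex-composition audit and the orphan-accessory scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import pandas as pd

from .completeness import assess_all, essential_gene_fraction, is_reliably_complete
from .lego import CompositionReport, audit_all, detect_paralog_localization_split
from .model import OxygenClass, PathwayProfile, Registry
from .nitrogen import infer_exchange_network, pathway_summary, pathway_profile
from .orthologs import ReductaseCalls, all_bbh_pairs, call_reductases, confirm_all
from .oxygen import ConsistencyReport, classify_oxygen, consistency_report
from .screen import FlaggedOperon, orphan_accessory_scan
from .simulate import Panel
from .summary import SummaryReport, summarize


@dataclass
class PipelineResult:
    panel: Panel
    genome_ids: List[str]
    completeness_counts: Dict[str, int]
    calls: ReductaseCalls
    classes: Dict[str, OxygenClass]
    consistency: ConsistencyReport
    profiles: Dict[str, PathwayProfile]
    pathway: Dict[str, object]
    edges: Set
    audits: List[CompositionReport]
    flagged_operons: List[FlaggedOperon]
    summary: SummaryReport
    essential_fractions: Dict[str, float] = field(default_factory=dict)

    @property
    def matrix(self) -> pd.DataFrame:
        return self.calls.matrix.loc[self.genome_ids]


def analyze_panel(
    panel: Panel,
    require_context: bool = True,
    window_k: int = 5,
    evalue_cutoff: float = 1e-20,
    include_n2o: bool = False,
) -> PipelineResult:
    registry = panel.registry
    ref_genome = panel.ground_truth.get("reference_genome", "REFSEED")
    genome_ids = [g for g in sorted(registry.genomes) if g != ref_genome]

    # 1. completeness
    assess_all(registry, panel.relatedness)
    completeness_counts: Dict[str, int] = {}
    for gid in genome_ids:
        v = registry.genomes[gid].completeness.value
        completeness_counts[v] = completeness_counts.get(v, 0) + 1

    ess_fracs = {
        gid: essential_gene_fraction(
            registry.genomes[gid], panel.essential_families, registry
        )
        for gid in genome_ids
    } if panel.essential_families else {}

    # 2. orthology and reductase calls
    pairs = all_bbh_pairs(
        panel.similarity,
        registry,
        [(gid, ref_genome) for gid in genome_ids],
        evalue_cutoff=evalue_cutoff,
    )
    confirmed = confirm_all(pairs, registry, window_k=window_k)
    calls = call_reductases(
        registry,
        confirmed,
        require_context=require_context,
        similarity=panel.similarity,
    )

    # 3. oxygen classes and label consistency
    classes = {
        gid: classify_oxygen(
            calls.presence_row(gid),
            registry.catalog,
            registry.genomes[gid].completeness,
        )
        for gid in genome_ids
    }
    consistency = consistency_report(classes, panel.metadata_labels)

    # 4. nitrogen-oxide profiles over reliable genomes only
    reliable = [
        gid for gid in genome_ids if is_reliably_complete(registry.genomes[gid])
    ]
    profiles = {
        gid: pathway_profile(gid, calls.presence_row(gid), registry.catalog)
        for gid in reliable
    }
    pathway = pathway_summary(profiles)
    edges = infer_exchange_network(
        profiles,
        {gid: classes[gid] for gid in reliable},
        include_n2o=include_n2o,
    )

    # 5. composition audit and orphan scan
    audits = audit_all(calls.instances, registry.catalog, registry)
    flagged = orphan_accessory_scan(registry, genome_ids=genome_ids)

    summary = summarize(
        registry,
        calls.matrix.loc[genome_ids],
        classes=classes,
        profiles=profiles,
    )
    return PipelineResult(
        panel=panel,
        genome_ids=genome_ids,
        completeness_counts=completeness_counts,
        calls=calls,
        classes=classes,
        consistency=consistency,
        profiles=profiles,
        pathway=pathway,
        edges=edges,
        audits=audits,
        flagged_operons=flagged,
        summary=summary,
        essential_fractions=ess_fracs,
    )
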