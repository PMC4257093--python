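"""Complex-composition audit ("Lego" principle).

Respiratory reductases are modular: the same catalytic subunit appears
with different rosters of membrane anchors, electron-transfer proteins
and maturation factors in different genomes, and sometimes with no
membrane component at all.  The audit annotates each called reductase
instance with its subunit-role completeness and predicted localization,
flags soluble variants (catalytic subunit without any membrane anchor),
and detects duplicated catalytic subunits whose copies diverge in
localization — candidate assimilatory duplicates.  The audit never
changes presence calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .model import Registry, ReductaseCatalogEntry, SubunitRole
from .orthologs import ReductaseInstance
from .screen import _subunit_families


@dataclass
class CompositionReport:
    genome_id: str
    entry: str
    catalytic_protein: str
    roles_present: Set[str] = field(default_factory=set)
    roles_absent: Set[str] = field(default_factory=set)
    predicted_localization: str = "cytoplasmic"
    soluble_variant: bool = False
    distally_encoded: bool = False  # missing anchors found elsewhere in genome


def _complex_localization(registry: Registry, protein_ids: Set[str]) -> str:
    """Cytoplasmic when no member is exported; membrane when any member
    has a TM segment; extracellular when export is by signal peptide only."""
    prots = [registry.proteins[p] for p in protein_ids]
    if any(p.tm_segments >= 1 for p in prots):
        return "membrane"
    if any(p.signal_peptide for p in prots):
        return "extracellular"
    return "cytoplasmic"


def _distal_accessory_present(
    registry: Registry,
    instance: ReductaseInstance,
    entry: ReductaseCatalogEntry,
) -> bool:
    """Genome-wide search for unlinked membrane-anchor homologs: anchors
    may be encoded far from the catalytic gene (distal operons)."""
    anchor_fams: Set[str] = set()
    for sub in entry.subunits:
        if sub.role is SubunitRole.MEMBRANE_ANCHOR:
            anchor_fams |= _subunit_families(registry, sub.reference)
    if not anchor_fams:
        return False
    local = instance.proteins()
    for prot in registry.proteins_of_genome(instance.genome_id):
        if prot.id in local:
            continue
        if prot.domain_families & anchor_fams:
            return True
    return False


def audit_complex(
    instance: ReductaseInstance,
    entry: ReductaseCatalogEntry,
    registry: Registry,
) -> CompositionReport:
    """Audit one called instance against its catalog entry's roster."""
    expected_roles = {s.role.value for s in entry.subunits}
    present = {SubunitRole.CATALYTIC.value} | {
        role for role, members in instance.members.items() if members
    }
    report = CompositionReport(
        genome_id=instance.genome_id,
        entry=instance.entry,
        catalytic_protein=instance.catalytic_protein,
        roles_present=present & expected_roles,
        roles_absent=expected_roles - present,
    )
    report.predicted_localization = _complex_localization(
        registry, instance.proteins()
    )
    anchors_expected = SubunitRole.MEMBRANE_ANCHOR.value in expected_roles
    anchors_absent = SubunitRole.MEMBRANE_ANCHOR.value in report.roles_absent
    if anchors_expected and anchors_absent:
        if _distal_accessory_present(registry, instance, entry):
            report.distally_encoded = True
        else:
            report.soluble_variant = True
    return report


def audit_all(
    instances: Sequence[ReductaseInstance],
    catalog: Mapping[str, ReductaseCatalogEntry],
    registry: Registry,
) -> List[CompositionReport]:
    return [
        audit_complex(inst, catalog[inst.entry], registry)
        for inst in instances
        if inst.entry in catalog
    ]


def detect_paralog_localization_split(
    genome_id: str,
    entry_name: str,
    reports: Sequence[CompositionReport],
) -> List[Tuple[str, str]]:
    """Pairs (membrane-associated copy, soluble cytoplasmic copy) of one
    catalytic subunit within a genome; candidate assimilatory duplicates
    arisen by duplication of the membrane-bound ancestor."""
    mine = [
        r
        for r in reports
        if r.genome_id == genome_id and r.entry == entry_name
    ]
    if len(mine) < 2:
        return []
    membrane = sorted(
        r.catalytic_protein
        for r in mine
        if r.predicted_localization in ("membrane", "extracellular")
    )
    soluble = sorted(
        r.catalytic_protein
        for r in mine
        if r.predicted_localization == "cytoplasmic"
    )
    return [(m, s) for m in membrane for s in soluble]
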