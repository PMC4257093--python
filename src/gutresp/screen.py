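"""Candidate-reductase screens.

Three screens share the operon model (maximal runs of same-strand,
same-contig genes with intergenic gaps below a threshold):

* the filter cascade for a flavin/thiol-dependent extracellular oxidase
  candidate — domain keyword match, then exported localization (signal
  peptide and/or transmembrane segment), then operon context with an
  oxygen/thiol-binding partner;
* the cross-strain co-occurrence filter that keeps only operons with an
  ortholog-complete counterpart in every strain of a panel;
* the orphan-accessory scan that flags operons carrying several accessory
  subunits of a known reductase but no catalytic subunit, together with a
  plausible alternative catalytic protein (the pattern behind the novel
  thiosulfate reductase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .catalog import DEFAULT_ALT_CATALYTIC_FAMILIES, DEFAULT_PARTNER_FAMILIES
from .model import Protein, Registry, ReductaseCatalogEntry, SubunitRole
from .orthologs import OrthologPair


@dataclass(frozen=True)
class Operon:
    genome_id: str
    genes: tuple  # ordered gene ids
    strand: str
    contig: str

    @property
    def id(self) -> str:
        return f"{self.genome_id}:{self.genes[0]}-{self.genes[-1]}"


def predict_operons(
    registry: Registry, genome_id: str, max_gap_bp: int = 300
) -> List[Operon]:
    """Maximal runs of same-strand, same-contig genes whose intergenic
    gaps do not exceed ``max_gap_bp``."""
    operons: List[Operon] = []
    genome = registry.genomes[genome_id]
    for contig in genome.contigs:
        order = registry.genes_on_contig(genome_id, contig)
        run: List[str] = []
        for gid in order:
            gene = registry.genes[gid]
            if run:
                prev = registry.genes[run[-1]]
                gap = gene.start - prev.end - 1
                if gene.strand != prev.strand or gap > max_gap_bp:
                    operons.append(
                        Operon(genome_id, tuple(run), prev.strand, contig)
                    )
                    run = []
            run.append(gid)
        if run:
            operons.append(
                Operon(
                    genome_id, tuple(run), registry.genes[run[-1]].strand, contig
                )
            )
    return operons


@dataclass
class CascadeTrace:
    """Membership at every stage of the candidate filter cascade."""

    families_keyword_matched: Set[str] = field(default_factory=set)
    families_with_genome_hits: Set[str] = field(default_factory=set)
    candidate_proteins: Set[str] = field(default_factory=set)
    localization_passed: Set[str] = field(default_factory=set)
    context_passed: Set[str] = field(default_factory=set)
    cooccurrence_passed: Set[str] = field(default_factory=set)

    def stage_sizes(self) -> Dict[str, int]:
        return {
            "families_keyword_matched": len(self.families_keyword_matched),
            "families_with_genome_hits": len(self.families_with_genome_hits),
            "candidate_proteins": len(self.candidate_proteins),
            "localization_passed": len(self.localization_passed),
            "context_passed": len(self.context_passed),
            "cooccurrence_passed": len(self.cooccurrence_passed),
        }


def family_partner_predicate(
    families: Iterable[str] = DEFAULT_PARTNER_FAMILIES,
) -> Callable[[Protein], bool]:
    """Partner test by domain-family membership (default: AhpC/TSA)."""
    fams = set(families)
    return lambda protein: bool(protein.domain_families & fams)


def run_cascade(
    registry: Registry,
    genome_id: str,
    keyword_family_set: Set[str],
    partner_predicate: Callable[[Protein], bool] = None,
    max_gap_bp: int = 300,
) -> CascadeTrace:
    """Filter cascade over one genome.

    Stage 1 keeps proteins whose domain families intersect the keyword
    set; stage 2 keeps exported proteins (signal peptide or >=1 TM
    segment); stage 3 keeps proteins whose operon contains a distinct
    partner protein satisfying ``partner_predicate``.
    """
    if partner_predicate is None:
        partner_predicate = family_partner_predicate()
    trace = CascadeTrace(families_keyword_matched=set(keyword_family_set))
    if not keyword_family_set:
        return trace
    proteins = registry.proteins_of_genome(genome_id)
    for prot in proteins:
        hit = prot.domain_families & keyword_family_set
        if hit:
            trace.families_with_genome_hits |= hit
            trace.candidate_proteins.add(prot.id)
    trace.localization_passed = {
        pid
        for pid in trace.candidate_proteins
        if registry.proteins[pid].exported
    }
    operon_of: Dict[str, Operon] = {}
    for op in predict_operons(registry, genome_id, max_gap_bp):
        for g in op.genes:
            operon_of[g] = op
    for pid in trace.localization_passed:
        gene_id = registry.proteins[pid].gene_id
        op = operon_of.get(gene_id)
        if op is None:
            continue
        partners = [
            registry.protein_for_gene(g)
            for g in op.genes
            if registry.genes[g].product_protein != pid
        ]
        if any(partner_predicate(p) for p in partners):
            trace.context_passed.add(pid)
    return trace


def cascade_operons(
    registry: Registry, trace: CascadeTrace, genome_id: str, max_gap_bp: int = 300
) -> List[Operon]:
    """Operons containing the cascade's context-passed candidates."""
    operon_of: Dict[str, Operon] = {}
    for op in predict_operons(registry, genome_id, max_gap_bp):
        for g in op.genes:
            operon_of[g] = op
    out: List[Operon] = []
    for pid in sorted(trace.context_passed):
        op = operon_of[registry.proteins[pid].gene_id]
        if op not in out:
            out.append(op)
    return out


def cooccurrence_filter(
    operons: Sequence[Operon],
    strain_panel: Sequence[str],
    registry: Registry,
    bbh_pairs: Set[OrthologPair],
    max_gap_bp: int = 300,
) -> List[Operon]:
    """Keep operons with an ortholog-complete counterpart in every panel
    strain: some operon of the strain must contain a BBH partner for each
    gene of the query operon.  An empty panel keeps everything."""
    partner_of: Dict[str, Set[str]] = {}
    for pair in bbh_pairs:
        partner_of.setdefault(pair.a, set()).add(pair.b)
        partner_of.setdefault(pair.b, set()).add(pair.a)
    strain_operons = {
        s: predict_operons(registry, s, max_gap_bp) for s in strain_panel
    }
    kept: List[Operon] = []
    for op in operons:
        query_proteins = [registry.genes[g].product_protein for g in op.genes]
        ok = True
        for strain in strain_panel:
            found = False
            for sop in strain_operons[strain]:
                sop_proteins = {
                    registry.genes[g].product_protein for g in sop.genes
                }
                if all(
                    partner_of.get(qp, set()) & sop_proteins
                    for qp in query_proteins
                ):
                    found = True
                    break
            if not found:
                ok = False
                break
        if ok:
            kept.append(op)
    return kept


@dataclass(frozen=True)
class FlaggedOperon:
    """Candidate novel-reductase operon from the orphan-accessory scan."""

    genome_id: str
    genes: tuple
    catalog_entry: str
    candidate_catalytic: str  # protein id
    accessory_hits: tuple  # (role, protein_id) pairs


ACCESSORY_ROLES = (
    SubunitRole.MEMBRANE_ANCHOR,
    SubunitRole.ELECTRON_TRANSFER,
    SubunitRole.MATURATION,
)


def _subunit_families(registry: Registry, reference: str) -> Set[str]:
    """Domain families standing for a subunit reference: the accession
    itself, or the families of the reference protein."""
    if reference in registry.proteins:
        return set(registry.proteins[reference].domain_families)
    return {reference}


def orphan_accessory_scan(
    registry: Registry,
    catalog: Optional[Mapping[str, ReductaseCatalogEntry]] = None,
    alt_catalytic_families: Iterable[str] = DEFAULT_ALT_CATALYTIC_FAMILIES,
    min_accessory: int = 2,
    max_gap_bp: int = 300,
    genome_ids: Optional[Sequence[str]] = None,
) -> List[FlaggedOperon]:
    """Flag operons carrying >= ``min_accessory`` accessory-subunit
    homologs of one catalog entry, no catalytic subunit of that entry,
    and a protein from a plausible alternative catalytic family."""
    catalog = catalog if catalog is not None else registry.catalog
    alt_fams = set(alt_catalytic_families)
    flagged: List[FlaggedOperon] = []
    for genome_id in genome_ids if genome_ids is not None else sorted(registry.genomes):
        for op in predict_operons(registry, genome_id, max_gap_bp):
            proteins = [registry.protein_for_gene(g) for g in op.genes]
            alt_candidates = [
                p.id for p in proteins if p.domain_families & alt_fams
            ]
            if not alt_candidates:
                continue
            for entry in catalog.values():
                cat_fams: Set[str] = set()
                for ref in entry.catalytic_references:
                    cat_fams |= _subunit_families(registry, ref)
                if any(p.domain_families & cat_fams for p in proteins):
                    continue
                hits = []
                for sub in entry.accessory_subunits:
                    fams = _subunit_families(registry, sub.reference)
                    for p in proteins:
                        if p.domain_families & fams:
                            hits.append((sub.role.value, p.id))
                if len({pid for _, pid in hits}) >= min_accessory:
                    flagged.append(
                        FlaggedOperon(
                            genome_id=genome_id,
                            genes=op.genes,
                            catalog_entry=entry.name,
                            candidate_catalytic=sorted(alt_candidates)[0],
                            accessory_hits=tuple(sorted(hits)),
                        )
                    )
    return flagged
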