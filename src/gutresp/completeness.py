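"""Draft-genome completeness assessment.

Two approaches are implemented.  The essential-gene fraction is kept as a
diagnostic only: even finished genomes can miss a sizeable share of a
generic essential-family list, so no threshold separates complete from
incomplete and the fraction never drives the verdict.  The adopted
criterion compares a draft's length against closely related finished
genomes: a draft at least as long as one finished relative is probably
complete, a shorter one is incomplete.  Relatives are found in tiers —
same species, then same genus, then highest 16S rRNA identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .model import Completeness, Genome, Registry, Status


@dataclass
class RelatednessProvider:
    """Taxon labels plus optional pairwise 16S identity scores.

    Identity scores are symmetric and lie in [0, 1]; they are consulted
    only when no finished genome shares the query's species or genus.
    """

    identities: Dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RelatednessProvider":
        """Build from a table with columns genome_a, genome_b, identity."""
        prov = cls()
        for row in table.itertuples(index=False):
            prov.set_identity(row.genome_a, row.genome_b, float(row.identity))
        return prov

    def set_identity(self, a: str, b: str, identity: float) -> None:
        if not (0.0 <= identity <= 1.0):
            raise ValueError(f"16S identity out of [0,1]: {identity}")
        self.identities[frozenset((a, b))] = identity

    def identity(self, a: str, b: str) -> Optional[float]:
        return self.identities.get(frozenset((a, b)))


def essential_gene_fraction(
    genome: Genome,
    essential_family_set: set,
    registry: Registry,
) -> float:
    """Fraction of essential domain families with at least one member
    protein in the genome.  Diagnostic only; never drives the verdict."""
    if not essential_family_set:
        raise ValueError("essential family set is empty")
    present = set()
    for prot in registry.proteins_of_genome(genome.id):
        present |= prot.domain_families & essential_family_set
    return len(present) / len(essential_family_set)


def find_related_finished(
    genome: Genome,
    registry: Registry,
    relatedness: Optional[RelatednessProvider] = None,
) -> List[Genome]:
    """Closest finished genomes by tier: same species, else same genus,
    else maximal 16S identity (all ties included).  Empty when no finished
    genome exists or no tier applies."""
    finished = [g for g in registry.finished_genomes() if g.id != genome.id]
    if not finished:
        return []
    same_species = [g for g in finished if genome.species and g.species == genome.species]
    if same_species:
        return same_species
    same_genus = [g for g in finished if genome.genus and g.genus == genome.genus]
    if same_genus:
        return same_genus
    if relatedness is not None:
        scored = [
            (g, relatedness.identity(genome.id, g.id))
            for g in finished
        ]
        scored = [(g, s) for g, s in scored if s is not None]
        if scored:
            best = max(s for _, s in scored)
            return [g for g, s in scored if s == best]
    return []


def assess_completeness_by_length(
    genome: Genome, related_finished: List[Genome]
) -> Completeness:
    """Length rule for drafts: probably complete iff at least as long as
    the shortest related finished genome (ties count as complete, since a
    draft equal in length to a finished relative shows no evidence of
    truncation)."""
    if genome.status is Status.FINISHED:
        return Completeness.COMPLETE
    if not related_finished:
        return Completeness.UNASSESSABLE
    threshold = min(g.length_bp for g in related_finished)
    if genome.length_bp >= threshold:
        return Completeness.PROBABLY_COMPLETE
    return Completeness.INCOMPLETE


def assess_all(
    registry: Registry,
    relatedness: Optional[RelatednessProvider] = None,
) -> Dict[str, int]:
    """Assess every genome in place and return the verdict counts.

    Finished genomes are complete by definition; drafts are assessed by
    the length rule.  The returned dict maps verdict value -> count and
    partitions the genome set.
    """
    counts: Dict[str, int] = {
        c.value: 0
        for c in (
            Completeness.COMPLETE,
            Completeness.PROBABLY_COMPLETE,
            Completeness.INCOMPLETE,
            Completeness.UNASSESSABLE,
        )
    }
    for genome in registry.genomes.values():
        if genome.status is Status.FINISHED:
            verdict = Completeness.COMPLETE
        else:
            related = find_related_finished(genome, registry, relatedness)
            verdict = assess_completeness_by_length(genome, related)
        genome.completeness = verdict
        counts[verdict.value] += 1
    return counts


def is_reliably_complete(genome: Genome) -> bool:
    """Finished or probably complete: lifestyle calls on these genomes can
    trust gene absences."""
    return genome.completeness in (
        Completeness.COMPLETE,
        Completeness.PROBABLY_COMPLETE,
    )
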