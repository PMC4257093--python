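"""Shared fixtures: generated panels are session-scoped since every
generator is deterministic under its seed."""

from __future__ import annotations

import pytest

from gutresp.model import Compartment, Gene, Genome, Protein, Registry, Status
from gutresp.pipeline import analyze_panel
from gutresp.simulate import (
    CascadeSpec,
    FamilySpec,
    PanelSpec,
    generate_cascade_fixture,
    generate_family_fixture,
    generate_panel,
)


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(PanelSpec.small(0))


@pytest.fixture(scope="session")
def small_result(small_panel):
    return analyze_panel(small_panel)


@pytest.fixture(scope="session")
def panel():
    """The calibrated default panel (254 genomes + reference)."""
    return generate_panel(PanelSpec(seed=0))


@pytest.fixture(scope="session")
def result(panel):
    return analyze_panel(panel)


@pytest.fixture(scope="session")
def cascade():
    return generate_cascade_fixture(CascadeSpec(seed=0))


@pytest.fixture(scope="session")
def family():
    return generate_family_fixture(FamilySpec(seed=0))


def make_genome(
    registry: Registry,
    genome_id: str,
    genes: list,
    taxon: str = "Testus testii",
    status: Status = Status.FINISHED,
    length_bp: int = 1_000_000,
) -> None:
    """Add a genome from (protein_id, start, end, strand, families,
    signal, tm) tuples on one contig."""
    registry.add_genome(
        Genome(id=genome_id, taxon=taxon, status=status, length_bp=length_bp)
    )
    contig = f"{genome_id}.c1"
    for pid, start, end, strand, families, signal, tm in genes:
        gene = Gene(
            id=f"{pid}.g",
            genome_id=genome_id,
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            product_protein=pid,
        )
        protein = Protein(
            id=pid,
            gene_id=gene.id,
            domain_families=set(families),
            signal_peptide=signal,
            tm_segments=tm,
            compartment=Compartment.MEMBRANE if tm else Compartment.UNKNOWN,
        )
        registry.add_gene(gene, protein)
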