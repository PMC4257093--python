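"""Core data model for the respiratory-capacity pipeline.

Genomes, genes, proteins and the cross-linked :class:`Registry` that every
downstream stage consumes.  Coordinates are 1-based inclusive throughout
(GFF convention); nothing else in the package converts coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple


class Status(str, Enum):
    FINISHED = "finished"
    DRAFT = "draft"


class Completeness(str, Enum):
    COMPLETE = "complete"
    PROBABLY_COMPLETE = "probably_complete"
    INCOMPLETE = "incomplete"
    UNASSESSABLE = "unassessable"
    UNSET = "unset"


class Compartment(str, Enum):
    CYTOPLASMIC = "cytoplasmic"
    MEMBRANE = "membrane"
    EXTRACELLULAR = "extracellular"
    PERIPLASMIC = "periplasmic"
    UNKNOWN = "unknown"


class SubunitRole(str, Enum):
    CATALYTIC = "catalytic"
    MEMBRANE_ANCHOR = "membrane_anchor"
    ELECTRON_TRANSFER = "electron_transfer"
    MATURATION = "maturation"


class Category(str, Enum):
    """Oxygen category of a reductase; ``NONE`` covers transporters and
    catalog extensions (e.g. hydrogenases) that never drive lifestyle calls."""

    AEROBIC = "aerobic"
    MICROAEROBIC = "microaerobic"
    ANAEROBIC = "anaerobic"
    NONE = "none"


class AssignmentMethod(str, Enum):
    KNOWN = "known"
    PHYLOGENY = "phylogeny"
    SDP = "sdp"
    UNASSIGNED = "unassigned"


class OxygenClassValue(str, Enum):
    AEROPHILIC = "aerophilic"
    MICROAEROPHILIC = "microaerophilic"
    ANAEROBIC = "anaerobic"
    AT_LEAST_MICROAEROPHILIC = "at_least_microaerophilic"
    MOST_LIKELY_ANAEROBIC = "most_likely_anaerobic"


@dataclass(frozen=True)
class OxygenClass:
    value: OxygenClassValue
    strong_microaerobe: bool = False

    def __post_init__(self) -> None:
        if self.strong_microaerobe and self.value not in (
            OxygenClassValue.MICROAEROPHILIC,
            OxygenClassValue.AT_LEAST_MICROAEROPHILIC,
        ):
            raise ValueError(
                "strong_microaerobe only applies to microaerophilic classes"
            )


@dataclass
class Gene:
    id: str
    genome_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    product_protein: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")


@dataclass
class Protein:
    id: str
    gene_id: str
    domain_families: Set[str] = field(default_factory=set)
    signal_peptide: bool = False
    tm_segments: int = 0
    compartment: Compartment = Compartment.UNKNOWN

    def __post_init__(self) -> None:
        if self.tm_segments < 0:
            raise ValueError(f"protein {self.id}: tm_segments < 0")

    @property
    def membrane_associated(self) -> bool:
        return self.tm_segments >= 1

    @property
    def exported(self) -> bool:
        return self.signal_peptide or self.tm_segments >= 1


@dataclass
class Genome:
    id: str
    taxon: str
    status: Status
    length_bp: int
    contigs: List[str] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    completeness: Completeness = Completeness.UNSET

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"genome {self.id}: length_bp must be positive")

    @property
    def genus(self) -> str:
        return self.taxon.split()[0] if self.taxon else ""

    @property
    def species(self) -> str:
        parts = self.taxon.split()
        return " ".join(parts[:2]) if len(parts) >= 2 else self.taxon


@dataclass(frozen=True)
class Subunit:
    role: SubunitRole
    reference: str  # reference protein id or domain-family accession


@dataclass
class ReductaseCatalogEntry:
    """One reductase type (Cyd, Nar, ...): oxygen category, substrate,
    and the subunit roster used for orthology calls and the complex audit."""

    name: str
    category: Category
    substrate: str
    subunits: List[Subunit]
    pathway_step: Optional[str] = None  # e.g. "NO3->NO2" or "transporter"
    mode: str = "respiratory"  # respiratory | assimilatory

    def __post_init__(self) -> None:
        if not any(s.role is SubunitRole.CATALYTIC for s in self.subunits):
            raise ValueError(f"catalog entry {self.name}: no catalytic subunit")
        if self.mode not in ("respiratory", "assimilatory"):
            raise ValueError(f"catalog entry {self.name}: bad mode {self.mode}")

    def references(self, role: SubunitRole) -> List[str]:
        return [s.reference for s in self.subunits if s.role is role]

    @property
    def catalytic_references(self) -> List[str]:
        return self.references(SubunitRole.CATALYTIC)

    @property
    def accessory_subunits(self) -> List[Subunit]:
        return [s for s in self.subunits if s.role is not SubunitRole.CATALYTIC]


@dataclass(frozen=True)
class SpecificityAssignment:
    protein_id: str
    specificity: str  # substrate name or "unknown"
    method: AssignmentMethod


@dataclass
class ScreenParams:
    """Tunable thresholds of the annotation screens.

    E-value cutoffs follow the two-tier convention: a strict orthology
    cutoff (1e-20 equivalent) and a permissive family-membership cutoff
    (1e-10 equivalent).
    """

    ortholog_evalue_cutoff: float = 1e-20
    family_evalue_cutoff: float = 1e-10
    sdp_max_gap_fraction: float = 0.5
    operon_max_gap_bp: int = 300
    context_window: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.sdp_max_gap_fraction <= 1):
            raise ValueError("sdp_max_gap_fraction must be in (0, 1]")


NITROGEN_STEPS: Tuple[str, ...] = (
    "NO3->NO2",
    "NO2->NH3",
    "NO2->NO",
    "NO->N2O",
    "N2O->N2",
)


@dataclass
class PathwayProfile:
    """Per-genome nitrogen-oxide capability map.

    ``steps`` maps every reduction step to the set of (enzyme, mode) pairs
    found in the genome; ``transporters`` collects nitrate/nitrite
    transporters such as NarK.
    """

    genome_id: str
    steps: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    transporters: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for step in NITROGEN_STEPS:
            self.steps.setdefault(step, set())
        extra = set(self.steps) - set(NITROGEN_STEPS)
        if extra:
            raise ValueError(f"unknown pathway steps: {sorted(extra)}")

    def enzymes(self, step: str, mode: Optional[str] = None) -> Set[str]:
        return {e for e, m in self.steps[step] if mode is None or m == mode}

    def has_step(self, step: str, mode: Optional[str] = None) -> bool:
        return bool(self.enzymes(step, mode))

    @property
    def empty(self) -> bool:
        return not any(self.steps.values()) and not self.transporters


@dataclass(frozen=True)
class ExchangeEdge:
    producer: str
    metabolite: str  # "nitrite" | "nitric_oxide" | "nitrous_oxide"
    consumer: str

    def __post_init__(self) -> None:
        if self.producer == self.consumer:
            raise ValueError("exchange edge producer == consumer")


class RegistryError(ValueError):
    """Raised when registry inputs fail cross-link validation; carries the
    full list of offending records."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "registry validation failed:\n" + "\n".join(self.problems)
        )


@dataclass
class Registry:
    """Cross-linked collection of genomes, genes, proteins and the catalog."""

    genomes: Dict[str, Genome] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    proteins: Dict[str, Protein] = field(default_factory=dict)
    catalog: Dict[str, ReductaseCatalogEntry] = field(default_factory=dict)
    _contig_order: Dict[Tuple[str, str], List[str]] = field(
        default_factory=dict, repr=False
    )

    # -- construction -----------------------------------------------------
    def add_genome(self, genome: Genome) -> None:
        self.genomes[genome.id] = genome

    def add_gene(self, gene: Gene, protein: Protein) -> None:
        self.genes[gene.id] = gene
        self.proteins[protein.id] = protein
        genome = self.genomes[gene.genome_id]
        genome.genes.append(gene.id)
        if gene.contig not in genome.contigs:
            genome.contigs.append(gene.contig)
        self._contig_order.pop((gene.genome_id, gene.contig), None)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        problems: List[str] = []
        for gene in self.genes.values():
            if gene.genome_id not in self.genomes:
                problems.append(f"gene {gene.id}: unknown genome {gene.genome_id}")
            if gene.product_protein not in self.proteins:
                problems.append(
                    f"gene {gene.id}: unresolvable protein link "
                    f"{gene.product_protein}"
                )
        for prot in self.proteins.values():
            if prot.gene_id not in self.genes:
                problems.append(f"protein {prot.id}: unknown gene {prot.gene_id}")
            if prot.compartment is Compartment.MEMBRANE and prot.tm_segments < 1:
                problems.append(
                    f"protein {prot.id}: membrane compartment with no TM segment"
                )
        for genome in self.genomes.values():
            if len(set(genome.genes)) != len(genome.genes):
                problems.append(f"genome {genome.id}: duplicate gene ids")
        if problems:
            raise RegistryError(problems)

    # -- lookups ----------------------------------------------------------
    def protein_for_gene(self, gene_id: str) -> Protein:
        return self.proteins[self.genes[gene_id].product_protein]

    def gene_for_protein(self, protein_id: str) -> Gene:
        return self.genes[self.proteins[protein_id].gene_id]

    def genome_of_protein(self, protein_id: str) -> str:
        return self.gene_for_protein(protein_id).genome_id

    def proteins_of_genome(self, genome_id: str) -> List[Protein]:
        return [
            self.proteins[self.genes[g].product_protein]
            for g in self.genomes[genome_id].genes
        ]

    def genes_on_contig(self, genome_id: str, contig: str) -> List[str]:
        """Gene ids on one contig ordered by start coordinate."""
        key = (genome_id, contig)
        if key not in self._contig_order:
            ids = [
                g
                for g in self.genomes[genome_id].genes
                if self.genes[g].contig == contig
            ]
            ids.sort(key=lambda g: (self.genes[g].start, self.genes[g].end, g))
            self._contig_order[key] = ids
        return self._contig_order[key]

    def neighbor_genes(self, gene_id: str, window_k: int) -> List[str]:
        """Up to ``window_k`` genes either side on the same contig,
        excluding the gene itself; truncated at contig edges."""
        gene = self.genes[gene_id]
        order = self.genes_on_contig(gene.genome_id, gene.contig)
        i = order.index(gene_id)
        lo = max(0, i - window_k)
        return [g for g in order[lo : i + window_k + 1] if g != gene_id]

    def finished_genomes(self) -> List[Genome]:
        return [g for g in self.genomes.values() if g.status is Status.FINISHED]
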