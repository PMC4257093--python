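"""Seeded synthetic-data generators.

Every fixture the pipeline consumes is generated here with planted
ground truth: a genome panel with reductase complements, operon
structure, ortholog similarity, localization features, lifestyle labels
and relatedness data; a five-strain panel for the candidate-reductase
cascade; and a family tree + alignment with planted specificity clades
and specificity-determining columns.

Generators specify *counts*, not probabilities, wherever a marginal is
calibrated, so downstream regression tests are exact.  All randomness
flows from the spec seed; two runs of the same spec produce identical
objects.  The default :class:`PanelSpec` encodes the study conditions of
the 254-genome human-gut reference set (55 finished genomes, 149
probably complete, 50 incomplete; 25/92/87 aerophilic/microaerophilic/
anaerobic among reliable genomes with 27 strong microaerobes; headline
reductase prevalences Cyd 126, Frd 93, Nrf 55, Nar 36, Nap 27, Dms 23,
Cyf 14; nitrogen-oxide route mix 28 complete ammonifiers, 1 denitrifier,
44 partial; label availability 98/136/5/15 with 42 and 14 planted
inconsistencies).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .catalog import default_catalog
from .completeness import RelatednessProvider
from .model import (
    Compartment,
    Gene,
    Genome,
    Protein,
    Registry,
    Status,
    SubunitRole,
)
from .orthologs import SimilarityTable

GENE_LEN = 900
INTRA_OPERON_GAP = 50
INTER_BLOCK_GAP = 800  # exceeds the operon gap rule, so blocks split

# Catalytic reference proteins that carry signal peptides (periplasmic /
# extracellular enzymes); everything else is cytoplasmic-facing.
_EXPORTED_CATALYTIC = {
    "REF_NRFA", "REF_NAPA", "REF_TORA", "REF_TSRA", "REF_CYFA", "REF_PHSA",
}
_MOLYBDOPTERIN_FAMILY = "PF00384"
_HEME_COPPER_FAMILY = "PF00115"
_MOLYBDOPTERIN_CATALYTIC = {
    "REF_NARG", "REF_NAPA", "REF_DMSA", "REF_TORA", "REF_TTRA", "REF_PHSA",
    "REF_YNFE", "REF_ARRA", "REF_ASRA", "REF_NASA",
}
_HEME_COPPER_CATALYTIC = {"REF_CYOB", "REF_QOXB", "REF_CTAD", "REF_CCON"}


def _ref_family(ref: str) -> str:
    return "FAM_" + ref.removeprefix("REF_")


def _evalue(bitscore: float) -> float:
    return 10.0 ** (-bitscore / 10.0)


class _Builder:
    """Accumulates genes, proteins and similarity rows for one registry."""

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)
        self.registry = Registry()
        self.registry.catalog = default_catalog()
        self.similarity_rows: List[tuple] = []
        self._cursor: Dict[Tuple[str, str], int] = {}
        self._gene_n = 0

    def add_genome(self, genome: Genome) -> None:
        self.registry.add_genome(genome)

    def add_gene(
        self,
        genome_id: str,
        contig: str,
        protein_id: str,
        families: Iterable[str] = (),
        signal: bool = False,
        tm: int = 0,
        gap: int = INTER_BLOCK_GAP,
        strand: str = "+",
    ) -> str:
        start = self._cursor.get((genome_id, contig), 1) + gap
        self._gene_n += 1
        gene_id = f"{protein_id}.g"
        compartment = (
            Compartment.MEMBRANE
            if tm >= 1
            else Compartment.EXTRACELLULAR
            if signal
            else Compartment.CYTOPLASMIC
        )
        gene = Gene(
            id=gene_id,
            genome_id=genome_id,
            contig=contig,
            start=start,
            end=start + GENE_LEN - 1,
            strand=strand,
            product_protein=protein_id,
        )
        protein = Protein(
            id=protein_id,
            gene_id=gene_id,
            domain_families=set(families),
            signal_peptide=signal,
            tm_segments=tm,
            compartment=compartment,
        )
        self.registry.add_gene(gene, protein)
        self._cursor[(genome_id, contig)] = gene.end
        return protein_id

    def link(self, a: str, b: str, bitscore: float) -> None:
        ev = _evalue(bitscore)
        self.similarity_rows.append((a, b, bitscore, ev))
        self.similarity_rows.append((b, a, bitscore, ev))

    def one_way(self, query: str, subject: str, bitscore: float) -> None:
        self.similarity_rows.append((query, subject, bitscore, _evalue(bitscore)))

    def similarity(self) -> SimilarityTable:
        return SimilarityTable(
            pd.DataFrame(
                self.similarity_rows,
                columns=["query", "subject", "bitscore", "evalue"],
            )
        )


def build_reference_genome(builder: _Builder, genome_id: str = "REFSEED") -> None:
    """One genome holding every catalog reference protein in operon
    layout, each entry followed by a conserved context-anchor gene."""
    builder.add_genome(
        Genome(
            id=genome_id,
            taxon="Refgenus reference",
            status=Status.FINISHED,
            length_bp=5_000_000,
        )
    )
    contig = f"{genome_id}.c1"
    for name in sorted(builder.registry.catalog):
        entry = builder.registry.catalog[name]
        first = True
        for sub in entry.subunits:
            ref = sub.reference
            if ref.startswith("REF_"):
                pid, fams = ref, {_ref_family(ref)}
            else:  # family-accession subunit: carrier protein
                pid, fams = f"REF_{name}_{ref}", {ref}
            if sub.role is SubunitRole.CATALYTIC:
                if ref in _MOLYBDOPTERIN_CATALYTIC:
                    fams = fams | {_MOLYBDOPTERIN_FAMILY}
                if ref in _HEME_COPPER_CATALYTIC:
                    fams = fams | {_HEME_COPPER_FAMILY}
            if pid in builder.registry.proteins:
                continue
            builder.add_gene(
                genome_id,
                contig,
                pid,
                families=fams,
                signal=ref in _EXPORTED_CATALYTIC,
                tm=2 if sub.role is SubunitRole.MEMBRANE_ANCHOR else 0,
                gap=INTER_BLOCK_GAP if first else INTRA_OPERON_GAP,
            )
            first = False
        builder.add_gene(
            genome_id,
            contig,
            f"REF_{name}_ANC",
            families={f"FAM_{name}_ANC"},
            gap=INTRA_OPERON_GAP,
        )


def plant_reductase(
    builder: _Builder,
    genome_id: str,
    contig: str,
    entry_name: str,
    copy: int = 1,
    primary: bool = True,
    soluble: bool = False,
    bare: bool = False,
    extracellular: bool = False,
) -> None:
    """Plant one copy of a reductase operon with ortholog similarity.

    ``primary`` copies carry the top bitscore and become the strict BBH;
    further copies score lower and are picked up as catalytic paralogs.
    ``soluble`` drops membrane anchors (adds an iron-sulfur partner
    instead) and clears the export signal; ``bare`` plants the catalytic
    subunit alone (cytoplasmic unless ``extracellular``).
    """
    entry = builder.registry.catalog[entry_name]
    tag = f"{genome_id}_{entry_name}{copy}"
    base_score = 520.0 if primary else 470.0 + float(builder.rng.integers(0, 30))
    first = True
    for sub in entry.subunits:
        if bare and sub.role is not SubunitRole.CATALYTIC:
            continue
        if soluble and sub.role is SubunitRole.MEMBRANE_ANCHOR:
            continue
        ref = sub.reference
        if ref.startswith("REF_"):
            fams = {_ref_family(ref)}
            if sub.role is SubunitRole.CATALYTIC:
                if ref in _MOLYBDOPTERIN_CATALYTIC:
                    fams |= {_MOLYBDOPTERIN_FAMILY}
                if ref in _HEME_COPPER_CATALYTIC:
                    fams |= {_HEME_COPPER_FAMILY}
            signal = ref in _EXPORTED_CATALYTIC
            if soluble or (bare and not extracellular):
                signal = False
            pid = builder.add_gene(
                genome_id,
                contig,
                f"{tag}_{ref.removeprefix('REF_')}",
                families=fams,
                signal=signal,
                tm=2 if sub.role is SubunitRole.MEMBRANE_ANCHOR else 0,
                gap=INTER_BLOCK_GAP if first else INTRA_OPERON_GAP,
            )
            score = base_score if sub.role is SubunitRole.CATALYTIC else 500.0
            builder.link(pid, ref, score)
        else:  # family-accession accessory: matched by domain content
            builder.add_gene(
                genome_id,
                contig,
                f"{tag}_{ref}",
                families={ref},
                tm=2 if sub.role is SubunitRole.MEMBRANE_ANCHOR else 0,
                gap=INTER_BLOCK_GAP if first else INTRA_OPERON_GAP,
            )
        first = False
    if soluble:
        builder.add_gene(
            genome_id,
            contig,
            f"{tag}_FES",
            families={"PF13247"},
            gap=INTRA_OPERON_GAP if not first else INTER_BLOCK_GAP,
        )
        first = False
    if primary and not (bare and not extracellular):
        # conserved context-anchor neighbour confirming the BBH
        anc = builder.add_gene(
            genome_id,
            contig,
            f"{tag}_ANC",
            families={f"FAM_{entry_name}_ANC"},
            gap=INTRA_OPERON_GAP if not first else INTER_BLOCK_GAP,
        )
        builder.link(anc, f"REF_{entry_name}_ANC", 450.0)


@dataclass
class PanelSpec:
    """Counts defining one synthetic genome panel (defaults: the study
    conditions of the 254-genome reference set; see module docstring).

    Counts are interlinked; :meth:`validate` rejects infeasible specs
    with an explanation.
    """

    seed: int = 0
    n_genomes: int = 254
    n_finished: int = 55
    n_probably_complete: int = 149
    n_incomplete: int = 50
    # oxygen classes among complete + probably complete genomes
    aero_complete: int = 25
    aero_without_micro: int = 1
    micro_complete: int = 92
    strong_micro: int = 27
    anaero_complete: int = 87
    # incomplete genomes
    aero_incomplete: int = 4
    micro_incomplete: int = 19
    # reductase prevalences (genome counts)
    cyd_total: int = 126
    cyf_total: int = 14
    cyf_and_cyd: int = 5
    frd_total: int = 93
    dms_total: int = 23
    dms_multi_copies: int = 12
    # nitrogen-oxide route mix (complete + probably complete only)
    ammonif_nar: int = 23
    ammonif_nap: int = 5
    extra_nap: int = 17
    nitrate_only_nar: int = 8
    nitrate_only_nap: int = 5
    nitrite_only_nrf: int = 27
    nar_nir: int = 1
    nar_nor: int = 3
    denitrifier: int = 1
    frd_only_anaero: int = 6
    nrf_paralog_split: int = 12
    nrf_soluble_only: int = 2
    # external-label availability and agreement
    n_both: int = 98
    n_both_inconsistent: int = 42
    n_metadata_only: int = 136
    n_metadata_only_inconsistent: int = 14
    n_assertion_only: int = 5
    # essential-gene diagnostic
    n_essential_families: int = 40
    essential_missing_in_worst: int = 6
    # similarity noise rows (sub-cutoff hits)
    n_noise_hits: int = 200

    @property
    def n_reliable(self) -> int:
        return self.n_finished + self.n_probably_complete

    @property
    def none_incomplete(self) -> int:
        return self.n_incomplete - self.aero_incomplete - self.micro_incomplete

    @property
    def micro_nonstrong(self) -> int:
        return self.micro_complete - self.strong_micro

    @property
    def partial_total(self) -> int:
        return (
            self.nitrate_only_nar
            + self.nitrate_only_nap
            + self.nitrite_only_nrf
            + self.nar_nir
            + self.nar_nor
        )

    @property
    def n_complete_ammonification(self) -> int:
        return self.ammonif_nar + self.ammonif_nap

    def validate(self) -> None:
        errs: List[str] = []
        if self.n_finished + self.n_probably_complete + self.n_incomplete != self.n_genomes:
            errs.append("completeness counts do not sum to n_genomes")
        if self.aero_complete + self.micro_complete + self.anaero_complete != self.n_reliable:
            errs.append("reliable-class counts do not sum to finished+probably")
        if self.none_incomplete < 0:
            errs.append("incomplete class counts exceed n_incomplete")
        micro_capable = (
            self.aero_complete
            - self.aero_without_micro
            + self.micro_complete
            + self.micro_incomplete
        )
        if micro_capable != self.cyd_total + self.cyf_total - self.cyf_and_cyd:
            errs.append(
                "microaerobic prevalences inconsistent with class design: "
                f"{micro_capable} micro-capable genomes vs Cyd {self.cyd_total} "
                f"+ Cyf {self.cyf_total} - overlap {self.cyf_and_cyd}"
            )
        if self.cyf_total > self.micro_complete:
            errs.append("cyf_total exceeds micro_complete")
        if self.strong_micro > self.micro_complete:
            errs.append("strong_micro exceeds micro_complete")
        if self.partial_total > self.micro_nonstrong:
            errs.append("partial nitrogen genomes exceed non-strong microaerophiles")
        n_anaero_n = self.n_complete_ammonification + self.denitrifier
        if n_anaero_n + self.frd_only_anaero > self.anaero_complete:
            errs.append("nitrogen-complete + Frd-only genomes exceed anaerobes")
        if self.extra_nap > self.ammonif_nar:
            errs.append("extra_nap exceeds ammonif_nar")
        if self.nrf_paralog_split + self.nrf_soluble_only > self.nitrite_only_nrf:
            errs.append("Nrf variant counts exceed nitrite-only genomes")
        frd_min = self.micro_nonstrong - self.partial_total
        frd_max = (
            self.micro_nonstrong
            + n_anaero_n
            + self.frd_only_anaero
        )
        if not (frd_min <= self.frd_total <= frd_max):
            errs.append(
                f"frd_total {self.frd_total} outside feasible [{frd_min}, {frd_max}]"
            )
        if self.dms_total - 2 > self.partial_total:
            errs.append("dms_total exceeds available carrier genomes")
        if self.dms_total >= 1 and self.ammonif_nar < min(self.dms_total, 2):
            errs.append("dms carriers require ammonifying host genomes")
        labelled = self.n_both + self.n_metadata_only + self.n_assertion_only
        if labelled > self.n_genomes:
            errs.append("label-availability groups exceed n_genomes")
        cyd_micro_complete = self.micro_complete - (self.cyf_total - self.cyf_and_cyd)
        if self.n_both_inconsistent > cyd_micro_complete:
            errs.append("n_both_inconsistent exceeds Cyd-bearing microaerophiles")
        if self.n_metadata_only_inconsistent > self.anaero_complete:
            errs.append("n_metadata_only_inconsistent exceeds anaerobes")
        if self.essential_missing_in_worst >= self.n_essential_families:
            errs.append("essential_missing_in_worst >= n_essential_families")
        if errs:
            raise ValueError("infeasible panel spec: " + "; ".join(errs))

    @classmethod
    def small(cls, seed: int = 0) -> "PanelSpec":
        """A 20-genome spec for fast end-to-end tests."""
        return cls(
            seed=seed,
            n_genomes=20,
            n_finished=6,
            n_probably_complete=9,
            n_incomplete=5,
            aero_complete=3,
            aero_without_micro=1,
            micro_complete=8,
            strong_micro=3,
            anaero_complete=4,
            aero_incomplete=1,
            micro_incomplete=2,
            cyd_total=11,
            cyf_total=2,
            cyf_and_cyd=1,
            frd_total=4,
            dms_total=1,
            dms_multi_copies=2,
            ammonif_nar=1,
            ammonif_nap=1,
            extra_nap=0,
            nitrate_only_nar=1,
            nitrate_only_nap=1,
            nitrite_only_nrf=2,
            nar_nir=0,
            nar_nor=1,
            denitrifier=1,
            frd_only_anaero=1,
            nrf_paralog_split=1,
            nrf_soluble_only=0,
            n_both=6,
            n_both_inconsistent=2,
            n_metadata_only=8,
            n_metadata_only_inconsistent=2,
            n_assertion_only=2,
            n_essential_families=10,
            essential_missing_in_worst=2,
            n_noise_hits=20,
        )


@dataclass
class Panel:
    """A generated panel: registry plus every side table and the planted
    ground truth."""

    registry: Registry
    similarity: SimilarityTable
    metadata_labels: pd.DataFrame
    relatedness: RelatednessProvider
    relatedness_table: pd.DataFrame
    essential_families: Set[str]
    ground_truth: Dict[str, object]


def generate_panel(spec: Optional[PanelSpec] = None) -> Panel:
    """Generate a genome panel with planted ground truth (see PanelSpec)."""
    spec = spec or PanelSpec()
    spec.validate()
    builder = _Builder(spec.seed)
    build_reference_genome(builder)
    rng = builder.rng

    n = spec.n_genomes
    width = max(3, len(str(n)))
    gids = [f"G{i + 1:0{width}d}" for i in range(n)]

    # ---- index layout (positions in gids) -------------------------------
    reliable = spec.n_reliable
    aero = list(range(0, spec.aero_complete))
    micro_lo = spec.aero_complete
    micro = list(range(micro_lo, micro_lo + spec.micro_complete))
    strong = micro[: spec.strong_micro]
    cyf_all = micro[: spec.cyf_total]
    cyf_with_cyd = cyf_all[: spec.cyf_and_cyd]
    cyf_only = cyf_all[spec.cyf_and_cyd :]
    nonstrong = micro[spec.strong_micro :]
    anaero_lo = micro_lo + spec.micro_complete
    anaero = list(range(anaero_lo, reliable))
    inc_lo = reliable
    inc_aero = list(range(inc_lo, inc_lo + spec.aero_incomplete))
    inc_micro = list(
        range(inc_lo + spec.aero_incomplete, inc_lo + spec.aero_incomplete + spec.micro_incomplete)
    )
    inc_none = list(range(inc_lo + spec.aero_incomplete + spec.micro_incomplete, n))

    # nitrogen-route genomes inside the non-strong microaerophiles
    cursor = 0

    def take(k: int) -> List[int]:
        nonlocal cursor
        out = nonstrong[cursor : cursor + k]
        cursor += k
        return out

    lacto = take(spec.nitrate_only_nar)
    nap_only = take(spec.nitrate_only_nap)
    nrf_only = take(spec.nitrite_only_nrf)
    nrf_split = nrf_only[: spec.nrf_paralog_split]
    nrf_sol = nrf_only[
        spec.nrf_paralog_split : spec.nrf_paralog_split + spec.nrf_soluble_only
    ]
    odo = take(spec.nar_nir)
    veillonella = take(spec.nar_nor)
    micro_filler = nonstrong[cursor:]
    partial = lacto + nap_only + nrf_only + odo + veillonella

    amm_nar = anaero[: spec.ammonif_nar]
    amm_nap = anaero[spec.ammonif_nar : spec.ammonif_nar + spec.ammonif_nap]
    extra_nap = amm_nar[: spec.extra_nap]
    k0 = spec.ammonif_nar + spec.ammonif_nap
    denitr = anaero[k0 : k0 + spec.denitrifier]
    frd_anaero = anaero[
        k0 + spec.denitrifier : k0 + spec.denitrifier + spec.frd_only_anaero
    ]
    anaero_zero = anaero[k0 + spec.denitrifier + spec.frd_only_anaero :]
    orphan_host = (frd_anaero or anaero_zero or anaero)[0] if anaero else None

    # Frd carriers: micro filler first, then nitrogen genomes, then the
    # dedicated Frd-only anaerobes, then partial genomes until the count.
    frd: List[int] = []
    for pool in (micro_filler, amm_nar, amm_nap, denitr, frd_anaero, partial):
        for i in pool:
            if len(frd) < spec.frd_total and i not in frd:
                frd.append(i)
    frd_set = set(frd)

    dms_multi = amm_nar[:1] if spec.dms_total >= 1 else []
    dms_second = amm_nar[1:2] if spec.dms_total >= 2 else []
    dms_rest = [i for i in partial if i in frd_set][: max(0, spec.dms_total - 2)]

    # ---- taxa, lengths, relatedness -------------------------------------
    n_genera = max(1, min(50, spec.n_finished))
    sixteen_s = []
    if spec.n_probably_complete >= 4 and spec.n_incomplete >= 3:
        sixteen_s = [spec.n_finished + 1, n - 2]  # one probably, one incomplete
    taxa: Dict[int, str] = {}
    for i in range(n):
        g = i % n_genera
        if i in sixteen_s:
            taxa[i] = f"Novigenus{i} isolate{i}"
        elif i < spec.n_finished or i % 2 == 0:
            taxa[i] = f"Genus{g:02d} species{g}"
        else:
            taxa[i] = f"Genus{g:02d} strain{i}"

    genus_min_len: Dict[str, int] = {}
    lengths: Dict[int, int] = {}
    for i in range(spec.n_finished):
        length = 3_000_000 + (i % n_genera) * 5_000 + int(rng.integers(0, 20_000))
        lengths[i] = length
        genus = taxa[i].split()[0]
        genus_min_len[genus] = min(genus_min_len.get(genus, 10**9), length)
    rel_rows: List[tuple] = []
    for i in range(spec.n_finished, n):
        genus = taxa[i].split()[0]
        if i in sixteen_s:
            # the first finished genomes serve as the 16S-closest matches
            best = gids[sixteen_s.index(i)]
            for j in range(spec.n_finished):
                ident = 0.97 if gids[j] == best else 0.82 + (j % 10) * 0.003
                rel_rows.append((gids[i], gids[j], round(ident, 4)))
            base = lengths[gids.index(best)]
        else:
            base = genus_min_len[genus]
        if i < reliable:
            lengths[i] = base + 5_000 + int(rng.integers(0, 50_000))
        else:
            lengths[i] = max(200_000, base - 200_000 - int(rng.integers(0, 200_000)))
    relatedness_table = pd.DataFrame(
        rel_rows, columns=["genome_a", "genome_b", "identity"]
    )
    relatedness = RelatednessProvider.from_table(relatedness_table)

    # ---- genomes, housekeeping and essential genes ----------------------
    essential = {f"ESS{k + 1:04d}" for k in range(spec.n_essential_families)}
    ess_sorted = sorted(essential)
    worst = 0  # a finished genome scores the panel's lowest essential fraction
    for i, gid in enumerate(gids):
        status = Status.FINISHED if i < spec.n_finished else Status.DRAFT
        builder.add_genome(
            Genome(id=gid, taxon=taxa[i], status=status, length_bp=lengths[i])
        )
        contig = f"{gid}.c1"
        for k in range(4):
            builder.add_gene(gid, contig, f"{gid}_HK{k}", gap=INTER_BLOCK_GAP)
        missing = 0
        if i == worst:
            missing = spec.essential_missing_in_worst
        elif i >= reliable:
            missing = int(rng.integers(0, min(3, spec.essential_missing_in_worst)))
        for fam in ess_sorted[: len(ess_sorted) - missing]:
            builder.add_gene(
                gid, contig, f"{gid}_{fam}", families={fam}, gap=INTER_BLOCK_GAP
            )

    # ---- reductase complements ------------------------------------------
    truth_red: Dict[str, Dict[str, int]] = {gid: {} for gid in gids}

    def plant(i: int, entry: str, **kw) -> None:
        gid = gids[i]
        copies = kw.pop("copies", 1)
        for c in range(copies):
            plant_reductase(
                builder,
                gid,
                f"{gid}.c1",
                entry,
                copy=c + 1,
                primary=(c == 0),
                **kw,
            )
        truth_red[gid][entry] = truth_red[gid].get(entry, 0) + copies

    for i in aero + inc_aero:
        plant(i, "Cta")
    for i in aero[spec.aero_without_micro :]:
        plant(i, "Cyd")
    for i in cyf_all:
        plant(i, "Cyf")
    for i in cyf_with_cyd:
        plant(i, "Cyd")
    for i in micro[spec.cyf_total :]:
        plant(i, "Cyd")
    for i in inc_micro:
        plant(i, "Cyd")

    for i in frd:
        plant(i, "Frd")
    for i in lacto:
        plant(i, "Nar")
        plant(i, "NarK")
    for i in nap_only:
        plant(i, "Nap")
    for i in nrf_only:
        if i in nrf_sol:
            plant(i, "Nrf", bare=True, extracellular=True)
        else:
            plant(i, "Nrf")
    for i in nrf_split:
        gid = gids[i]
        plant_reductase(
            builder, gid, f"{gid}.c1", "Nrf", copy=2, primary=False, bare=True
        )
        truth_red[gid]["Nrf"] += 1
    for i in odo:
        plant(i, "Nar")
        plant(i, "Nir")
    for i in veillonella:
        plant(i, "Nar")
        plant(i, "Nor")
    for i in amm_nar:
        plant(i, "Nar")
        plant(i, "Nrf")
    for i in extra_nap:
        plant(i, "Nap")
    for i in amm_nap:
        plant(i, "Nap")
        plant(i, "Nrf")
    for i in denitr:
        plant(i, "Nar")
        plant(i, "Nir")
        plant(i, "Nor")
        plant(i, "Nos")
    for i in dms_multi:
        plant(i, "Dms", copies=spec.dms_multi_copies)
        plant(i, "Tor", soluble=True)
    for i in dms_second:
        plant(i, "Dms", copies=3)
        plant(i, "Tor", soluble=True)
    for i in dms_rest:
        plant(i, "Dms")

    # orphan accessory operon (novel thiosulfate-reductase pattern):
    # several Nos accessory homologs, no NosZ, plus a c-type cytochrome
    if orphan_host is not None:
        gid = gids[orphan_host]
        contig = f"{gid}.c1"
        builder.add_gene(gid, contig, f"{gid}_ORPH_CYT", families={"PF02335"},
                         signal=True, gap=INTER_BLOCK_GAP)
        builder.add_gene(gid, contig, f"{gid}_ORPH_NOSD", families={"PF05048"},
                         gap=INTRA_OPERON_GAP)
        builder.add_gene(gid, contig, f"{gid}_ORPH_NOSL", families={"PF05573"},
                         gap=INTRA_OPERON_GAP)
        builder.add_gene(gid, contig, f"{gid}_ORPH_NOSY", families={"PF05140"},
                         tm=2, gap=INTRA_OPERON_GAP)

    # ---- noise similarity hits (below the orthology cutoff) -------------
    ref_prots = sorted(
        p for p in builder.registry.proteins if p.startswith("REF_")
    )
    genome_prots = sorted(
        p for p in builder.registry.proteins if not p.startswith("REF_")
    )
    for _ in range(spec.n_noise_hits):
        q = genome_prots[int(rng.integers(0, len(genome_prots)))]
        s = ref_prots[int(rng.integers(0, len(ref_prots)))]
        builder.one_way(q, s, 80.0 + float(rng.integers(0, 70)))

    # ---- external labels -------------------------------------------------
    consistent_label = {
        "aerophilic": "aerobe",
        "microaerophilic": "microaerophile",
        "at_least_microaerophilic": "microaerophile",
        "anaerobic": "anaerobe",
        "most_likely_anaerobic": "anaerobe",
    }
    klass: Dict[int, str] = {}
    for i in aero + inc_aero:
        klass[i] = "aerophilic"
    for i in micro:
        klass[i] = "microaerophilic"
    for i in inc_micro:
        klass[i] = "at_least_microaerophilic"
    for i in anaero:
        klass[i] = "anaerobic"
    for i in inc_none:
        klass[i] = "most_likely_anaerobic"

    cyd_micro = [i for i in micro if i not in cyf_only]
    both_inc = cyd_micro[-spec.n_both_inconsistent :] if spec.n_both_inconsistent else []
    anaero_like = anaero + inc_none
    md_inc = (
        anaero_like[-spec.n_metadata_only_inconsistent :]
        if spec.n_metadata_only_inconsistent
        else []
    )
    used = set(both_inc) | set(md_inc)
    remaining = [i for i in range(n) if i not in used]
    both_cons = remaining[: spec.n_both - spec.n_both_inconsistent]
    remaining = remaining[len(both_cons) :]
    md_cons = remaining[: spec.n_metadata_only - spec.n_metadata_only_inconsistent]
    remaining = remaining[len(md_cons) :]
    assertion_only = remaining[: spec.n_assertion_only]
    label_rows: List[tuple] = []
    for i in both_inc:
        label_rows.append((gids[i], "metadata", "anaerobe"))
        label_rows.append((gids[i], "assertion", consistent_label[klass[i]]))
    for i in both_cons:
        label_rows.append((gids[i], "metadata", consistent_label[klass[i]]))
        label_rows.append((gids[i], "assertion", consistent_label[klass[i]]))
    for i in md_inc:
        label_rows.append((gids[i], "metadata", "aerobe"))
    for i in md_cons:
        label_rows.append((gids[i], "metadata", consistent_label[klass[i]]))
    for i in assertion_only:
        label_rows.append((gids[i], "assertion", consistent_label[klass[i]]))
    metadata_labels = pd.DataFrame(
        label_rows, columns=["genome_id", "source", "label"]
    )

    builder.registry.validate()

    ground_truth: Dict[str, object] = {
        "spec": asdict(spec),
        "genome_ids": gids,
        "reference_genome": "REFSEED",
        "classes": {gids[i]: klass[i] for i in range(n)},
        "strong_microaerobes": [gids[i] for i in strong],
        "completeness": {
            gids[i]: (
                "complete"
                if i < spec.n_finished
                else "probably_complete"
                if i < reliable
                else "incomplete"
            )
            for i in range(n)
        },
        "reductases": truth_red,
        "essential_worst": {
            "genome": gids[worst],
            "fraction": (spec.n_essential_families - spec.essential_missing_in_worst)
            / spec.n_essential_families,
        },
        "nitrogen": {
            "complete_ammonification": [gids[i] for i in amm_nar + amm_nap],
            "complete_denitrification": [gids[i] for i in denitr],
            "partial": [gids[i] for i in partial],
            "producer_only_nitrite": [gids[i] for i in lacto + nap_only],
            "consumer_only_nitrite": [gids[i] for i in nrf_only],
            "producer_nitric_oxide": [gids[i] for i in odo],
            "consumer_nitric_oxide": [gids[i] for i in veillonella],
        },
        "lego": {
            "soluble_tor": [gids[i] for i in dms_multi + dms_second],
            "nrf_paralog_split": [gids[i] for i in nrf_split],
            "nrf_soluble_only": [gids[i] for i in nrf_sol],
            "multi_copy_dms": {gids[i]: spec.dms_multi_copies for i in dms_multi},
        },
        "orphan_operon_genome": gids[orphan_host] if orphan_host is not None else None,
        "labels": {
            "both": [gids[i] for i in both_inc + both_cons],
            "both_inconsistent": [gids[i] for i in both_inc],
            "metadata_only": [gids[i] for i in md_inc + md_cons],
            "metadata_only_inconsistent": [gids[i] for i in md_inc],
            "assertion_only": [gids[i] for i in assertion_only],
        },
    }
    return Panel(
        registry=builder.registry,
        similarity=builder.similarity(),
        metadata_labels=metadata_labels,
        relatedness=relatedness,
        relatedness_table=relatedness_table,
        essential_families=essential,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# cascade fixture: a focal genome plus a strain panel for the candidate
# microaerobic-reductase screen
# ---------------------------------------------------------------------------


@dataclass
class CascadeSpec:
    """Counts for the candidate-screen fixture (defaults: the study
    cascade — 187 keyword families, 42 with genome hits, 75 candidate
    proteins, 7 exported, 3 in partnered operons, 2 of 3 operons shared
    by all five strains)."""

    seed: int = 0
    n_keyword_families: int = 187
    n_families_with_hits: int = 42
    n_candidates: int = 75
    n_localized: int = 7
    n_context: int = 3
    n_strains: int = 5
    n_operons_shared: int = 2

    def validate(self) -> None:
        errs: List[str] = []
        if not (0 <= self.n_context <= self.n_localized <= self.n_candidates):
            errs.append("cascade counts must be monotone: context <= localized <= candidates")
        if self.n_families_with_hits > min(self.n_keyword_families, self.n_candidates):
            errs.append("families_with_hits exceeds keyword families or candidates")
        if self.n_operons_shared > self.n_context:
            errs.append("shared operons exceed context-passed operons")
        if self.n_strains < 1:
            errs.append("panel needs >= 1 strain")
        if errs:
            raise ValueError("infeasible cascade spec: " + "; ".join(errs))


@dataclass
class CascadeFixture:
    registry: Registry
    similarity: SimilarityTable
    focal_genome: str
    strain_panel: List[str]
    keyword_families: Set[str]
    ground_truth: Dict[str, object]


def generate_cascade_fixture(spec: Optional[CascadeSpec] = None) -> CascadeFixture:
    spec = spec or CascadeSpec()
    spec.validate()
    builder = _Builder(spec.seed + 7)
    strains = [f"FP{k + 1:02d}" for k in range(spec.n_strains)]
    for s in strains:
        builder.add_genome(
            Genome(
                id=s,
                taxon="Faecalibact prausnitzii-like",
                status=Status.FINISHED,
                length_bp=600_000,
            )
        )
    focal = strains[0]
    contig = f"{focal}.c1"
    keyword = {f"KW{k + 1:04d}" for k in range(spec.n_keyword_families)}
    kw_sorted = sorted(keyword)

    context_ids: List[str] = []
    operon_map: Dict[str, List[str]] = {}
    for j in range(spec.n_candidates):
        fam = kw_sorted[j % spec.n_families_with_hits]
        pid = f"{focal}_CAND{j + 1:03d}"
        if j < spec.n_context:
            # partnered operon: exported candidate + oxygen/thiol partner
            builder.add_gene(focal, contig, pid, families={fam}, signal=True,
                             gap=INTER_BLOCK_GAP)
            partner = builder.add_gene(
                focal, contig, f"{focal}_PART{j + 1}", families={"PF00578"},
                gap=INTRA_OPERON_GAP,
            )
            context_ids.append(pid)
            operon_map[pid] = [pid, partner]
        elif j < spec.n_localized:
            # exported but isolated: no partner in the operon
            builder.add_gene(focal, contig, pid, families={fam}, tm=1,
                             gap=INTER_BLOCK_GAP)
        else:
            builder.add_gene(focal, contig, pid, families={fam},
                             gap=INTER_BLOCK_GAP)

    # counterpart operons in the other strains (one operon missing from
    # the last strain, mirroring the excluded third candidate operon)
    for k, pid in enumerate(context_ids):
        carriers = strains[1:] if k < spec.n_operons_shared else strains[1:-1]
        for s in carriers:
            c = f"{s}.c1"
            a = builder.add_gene(s, c, f"{s}_CAND{k + 1:03d}",
                                 families={kw_sorted[k % spec.n_families_with_hits]},
                                 signal=True, gap=INTER_BLOCK_GAP)
            b = builder.add_gene(s, c, f"{s}_PART{k + 1}", families={"PF00578"},
                                 gap=INTRA_OPERON_GAP)
            builder.link(a, operon_map[pid][0], 400.0)
            builder.link(b, operon_map[pid][1], 390.0)
    # housekeeping filler so every strain has non-candidate genes
    for s in strains:
        for k in range(3):
            builder.add_gene(s, f"{s}.c1", f"{s}_HK{k}", gap=INTER_BLOCK_GAP)

    builder.registry.validate()
    survivors = context_ids[: spec.n_operons_shared]
    ground_truth: Dict[str, object] = {
        "spec": asdict(spec),
        "stage_sizes": {
            "families_keyword_matched": spec.n_keyword_families,
            "families_with_genome_hits": spec.n_families_with_hits,
            "candidate_proteins": spec.n_candidates,
            "localization_passed": spec.n_localized,
            "context_passed": spec.n_context,
            "cooccurrence_passed": spec.n_operons_shared,
        },
        "context_candidates": context_ids,
        "surviving_candidates": survivors,
    }
    return CascadeFixture(
        registry=builder.registry,
        similarity=builder.similarity(),
        focal_genome=focal,
        strain_panel=strains[1:],
        keyword_families=keyword,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# family fixture: tree with planted specificity clades + SDP alignment
# ---------------------------------------------------------------------------

FAMILY_SUBSTRATES = (
    "nitrate", "nitrite", "DMSO/TMAO", "TMAO",
    "thiosulfate", "tetrathionate", "arsenate", "fumarate",
    "selenate", "sulfite", "adenylyl sulfate", "polysulfide",
)


@dataclass
class FamilySpec:
    """Counts for the catalytic-subunit family fixture: planted
    monophyletic specificity clades with conserved context, plus detached
    members recoverable only through SDP classification."""

    seed: int = 0
    n_tips: int = 100
    n_clades: int = 8
    known_fraction: float = 0.25
    sdp_noise: float = 0.05
    n_detached: int = 8
    aln_len: int = 60
    n_sdp_columns: int = 10

    def validate(self) -> None:
        errs: List[str] = []
        if self.n_clades < 2:
            errs.append("SDP classification needs >= 2 specificity groups")
        if self.n_clades > len(FAMILY_SUBSTRATES):
            errs.append("too many clades for the substrate list")
        if self.n_tips - self.n_detached < 3 * self.n_clades:
            errs.append("clades need >= 3 tips each")
        if not (0.0 < self.known_fraction <= 1.0):
            errs.append("known_fraction must be in (0, 1]")
        if not (0.0 <= self.sdp_noise < 0.5):
            errs.append("sdp_noise must be in [0, 0.5)")
        if self.n_sdp_columns > self.aln_len:
            errs.append("more SDP columns than alignment columns")
        if errs:
            raise ValueError("infeasible family spec: " + "; ".join(errs))


@dataclass
class FamilyFixture:
    tree: "FamilyTree"
    alignment: Dict[str, str]
    newick: str
    ground_truth: Dict[str, object]


def generate_family_fixture(spec: Optional[FamilySpec] = None) -> FamilyFixture:
    from .specificity import AMINO_ACIDS, FamilyTree
    import dendropy

    spec = spec or FamilySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed + 13)

    n_claded = spec.n_tips - spec.n_detached
    sizes = [n_claded // spec.n_clades] * spec.n_clades
    for k in range(n_claded - sum(sizes)):
        sizes[k] += 1
    groups = list(FAMILY_SUBSTRATES[: spec.n_clades])

    tip_group: Dict[str, str] = {}
    known: Dict[str, str] = {}
    contexts: Dict[str, Set[str]] = {}
    detached: List[str] = []
    clade_newicks: List[str] = []
    t = 0
    for c, size in enumerate(sizes):
        tips = []
        for _ in range(size):
            t += 1
            tip = f"T{t:03d}"
            tips.append(tip)
            tip_group[tip] = groups[c]
            contexts[tip] = {f"CTX{c:02d}"}
        n_known = max(2, math.ceil(spec.known_fraction * size))
        for tip in tips[:n_known]:
            known[tip] = groups[c]
        sub = f"{tips[0]}:0.01"
        for tip in tips[1:]:
            sub = f"({sub},{tip}:0.01):0.01"
        clade_newicks.append(f"({sub}):1.0")
    for d in range(spec.n_detached):
        t += 1
        tip = f"T{t:03d}"
        detached.append(tip)
        tip_group[tip] = groups[d % spec.n_clades]
        contexts[tip] = {f"CTXD{d:02d}"}
    if detached:
        sub = f"{detached[0]}:0.02"
        for tip in detached[1:]:
            sub = f"({sub},{tip}:0.02):0.02"
        clade_newicks.append(f"({sub}):1.0")
    newick = "[&R] (" + ",".join(clade_newicks) + "):0.0;"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True

    group_index = {g: i for i, g in enumerate(groups)}
    aln: Dict[str, str] = {}
    consensus = [
        AMINO_ACIDS[int(rng.integers(0, 20))] for _ in range(spec.aln_len)
    ]
    for tip, grp in tip_group.items():
        g = group_index[grp]
        chars: List[str] = []
        for col in range(spec.aln_len):
            if col < spec.n_sdp_columns:
                aa = AMINO_ACIDS[(3 * g + col) % 20]
                if rng.random() < spec.sdp_noise:
                    aa = AMINO_ACIDS[int(rng.integers(0, 20))]
            else:
                aa = consensus[col]
                r = rng.random()
                if r < 0.03:
                    aa = "-"
                elif r < 0.13:
                    aa = AMINO_ACIDS[int(rng.integers(0, 20))]
            chars.append(aa)
        aln[tip] = "".join(chars)

    ground_truth: Dict[str, object] = {
        "spec": asdict(spec),
        "tip_group": dict(tip_group),
        "known": dict(known),
        "detached": list(detached),
        "sdp_columns": list(range(spec.n_sdp_columns)),
        "groups": groups,
    }
    return FamilyFixture(
        tree=FamilyTree(tree=tree, known=known, contexts=contexts),
        alignment=aln,
        newick=newick,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# fixture-directory serialization
# ---------------------------------------------------------------------------


def write_panel(panel: Panel, outdir) -> None:
    """Write a panel as a plain-text fixture directory (GFF3, TSVs, YAML,
    ground-truth JSON)."""
    import json
    from pathlib import Path

    from .catalog import dump_catalog
    from .io import write_essential_families, write_registry_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_registry_tables(panel.registry, outdir)
    panel.similarity.to_tsv(outdir / "similarity.tsv")
    dump_catalog(panel.registry.catalog, outdir / "catalog.yaml")
    panel.metadata_labels.to_csv(
        outdir / "metadata_labels.tsv", sep="\t", index=False
    )
    panel.relatedness_table.to_csv(
        outdir / "relatedness.tsv", sep="\t", index=False
    )
    write_essential_families(panel.essential_families, outdir / "essential_families.txt")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(panel.ground_truth, fh, indent=1, sort_keys=True)


def write_family_fixture(fixture: FamilyFixture, outdir) -> None:
    import json
    from pathlib import Path

    from .io import write_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(fixture.newick + "\n")
    write_alignment(fixture.alignment, outdir / "alignment.fasta")
    pd.DataFrame(
        [
            {"protein_id": t, "specificity": s}
            for t, s in sorted(fixture.tree.known.items())
        ]
    ).to_csv(outdir / "known.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"protein_id": t, "context": ";".join(sorted(c))}
            for t, c in sorted(fixture.tree.contexts.items())
        ]
    ).to_csv(outdir / "context.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(fixture.ground_truth, fh, indent=1, sort_keys=True)


def load_panel_dir(path) -> Panel:
    """Reload a fixture directory written by :func:`write_panel`."""
    import json
    from pathlib import Path

    from .io import (
        load_fixture_dir,
        read_essential_families,
        read_metadata_labels,
        read_similarity,
    )

    path = Path(path)
    registry = load_fixture_dir(path)
    rel_path = path / "relatedness.tsv"
    rel_table = (
        pd.read_csv(rel_path, sep="\t")
        if rel_path.exists()
        else pd.DataFrame(columns=["genome_a", "genome_b", "identity"])
    )
    gt_path = path / "ground_truth.json"
    ground_truth: Dict[str, object] = {}
    if gt_path.exists():
        with open(gt_path) as fh:
            ground_truth = json.load(fh)
    ess_path = path / "essential_families.txt"
    labels_path = path / "metadata_labels.tsv"
    labels = (
        read_metadata_labels(labels_path)
        if labels_path.exists()
        else pd.DataFrame(columns=["genome_id", "source", "label"])
    )
    return Panel(
        registry=registry,
        similarity=read_similarity(path / "similarity.tsv"),
        metadata_labels=labels,
        relatedness=RelatednessProvider.from_table(rel_table),
        relatedness_table=rel_table,
        essential_families=read_essential_families(ess_path)
        if ess_path.exists()
        else set(),
        ground_truth=ground_truth,
    )
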