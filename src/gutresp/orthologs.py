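"""Orthology by best bidirectional hits (BBH) with genomic-context support.

Reductase presence in a genome is called when a catalytic subunit of a
catalog entry has a context-confirmed BBH ortholog there.  Context
confirmation requires at least one additional BBH pair linking the two
genes' neighbourhoods, the classic synteny check that separates orthologs
from stray best hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .model import (
    Registry,
    ReductaseCatalogEntry,
    ScreenParams,
    Subunit,
    SubunitRole,
)

SIMILARITY_COLUMNS = ("query", "subject", "bitscore", "evalue")


class SimilarityTable:
    """Directed pairwise similarity scores (BLAST-tabular style).

    At most one row is kept per ordered (query, subject) pair — the best
    HSP by bitscore, ties broken toward the smaller e-value.
    """

    def __init__(self, rows: pd.DataFrame):
        df = rows.loc[:, list(SIMILARITY_COLUMNS)].copy()
        if (df["evalue"] < 0).any():
            raise ValueError("negative e-value in similarity table")
        df = df.sort_values(
            ["query", "subject", "bitscore", "evalue"],
            ascending=[True, True, False, True],
            kind="mergesort",
        ).drop_duplicates(["query", "subject"], keep="first")
        self._df = df.reset_index(drop=True)

    @classmethod
    def from_blast_tab(cls, path) -> "SimilarityTable":
        """Load a BLAST outfmt-6 style file; only the query, subject,
        bitscore and e-value columns are used."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] == 4:
            df.columns = list(SIMILARITY_COLUMNS)
        elif df.shape[1] >= 12:
            df = df.iloc[:, [0, 1, 10, 11]]
            df.columns = ["query", "subject", "evalue", "bitscore"]
            df = df[["query", "subject", "bitscore", "evalue"]]
        else:
            raise ValueError(
                f"unrecognised similarity table with {df.shape[1]} columns"
            )
        return cls(df)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "SimilarityTable":
        return cls(pd.DataFrame(records, columns=list(SIMILARITY_COLUMNS)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def to_tsv(self, path) -> None:
        self._df.to_csv(path, sep="\t", index=False)

    def best_hits(self, registry: Registry) -> Dict[Tuple[str, str], Tuple[str, float]]:
        """Best subject per (query, subject-genome): ties broken by higher
        bitscore, then lexicographically smallest subject id.

        Returns (query, subject_genome) -> (subject, evalue).
        """
        df = self._df[self._df["subject"].isin(registry.proteins.keys())].copy()
        genome_of = {
            pid: registry.genome_of_protein(pid) for pid in df["subject"].unique()
        }
        df["subject_genome"] = df["subject"].map(genome_of)
        df = df.sort_values(
            ["query", "subject_genome", "bitscore", "subject"],
            ascending=[True, True, False, True],
            kind="mergesort",
        ).drop_duplicates(["query", "subject_genome"], keep="first")
        return {
            (row.query, row.subject_genome): (row.subject, row.evalue)
            for row in df.itertuples(index=False)
        }


@dataclass(frozen=True)
class OrthologPair:
    """Unordered BBH pair; members stored in sorted order."""

    a: str
    b: str
    context_confirmed: bool = False

    def __post_init__(self):
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @property
    def members(self) -> FrozenSet[str]:
        return frozenset((self.a, self.b))

    def partner(self, protein_id: str) -> str:
        if protein_id == self.a:
            return self.b
        if protein_id == self.b:
            return self.a
        raise KeyError(protein_id)


def best_bidirectional_hits(
    similarity: SimilarityTable,
    registry: Registry,
    genome_a: str,
    genome_b: str,
    evalue_cutoff: float = 1e-20,
    _best: Optional[Dict] = None,
) -> Set[OrthologPair]:
    """BBH pairs between two genomes at the orthology e-value cutoff.

    (a, b) pairs iff b is a's best subject in genome_b, a is b's best in
    genome_a, and both directions pass the cutoff.  Symmetric in its
    genome arguments.
    """
    best = _best if _best is not None else similarity.best_hits(registry)
    pairs: Set[OrthologPair] = set()
    a_proteins = {p.id for p in registry.proteins_of_genome(genome_a)}
    for pid in sorted(a_proteins):
        hit = best.get((pid, genome_b))
        if hit is None:
            continue
        subject, ev_fwd = hit
        back = best.get((subject, genome_a))
        if back is None:
            continue
        partner, ev_rev = back
        if partner != pid:
            continue
        if ev_fwd <= evalue_cutoff and ev_rev <= evalue_cutoff:
            pairs.add(OrthologPair(*sorted((pid, subject))))
    return pairs


def all_bbh_pairs(
    similarity: SimilarityTable,
    registry: Registry,
    genome_pairs: Iterable[Tuple[str, str]],
    evalue_cutoff: float = 1e-20,
) -> Set[OrthologPair]:
    """BBH pairs over many genome pairs, sharing one best-hit index."""
    best = similarity.best_hits(registry)
    pairs: Set[OrthologPair] = set()
    for ga, gb in genome_pairs:
        pairs |= best_bidirectional_hits(
            similarity, registry, ga, gb, evalue_cutoff, _best=best
        )
    return pairs


def confirm_context(
    pair: OrthologPair,
    registry: Registry,
    bbh_pairs: Set[OrthologPair],
    window_k: int = 5,
) -> bool:
    """True iff another BBH pair links genes within +/- ``window_k`` genes
    of each member.  Windows truncate at contig edges; a gene alone on its
    contig is never confirmed."""
    gene_a = registry.gene_for_protein(pair.a)
    gene_b = registry.gene_for_protein(pair.b)
    neigh_a = {
        registry.genes[g].product_protein
        for g in registry.neighbor_genes(gene_a.id, window_k)
    }
    neigh_b = {
        registry.genes[g].product_protein
        for g in registry.neighbor_genes(gene_b.id, window_k)
    }
    for other in bbh_pairs:
        if other.members == pair.members:
            continue
        if (other.a in neigh_a and other.b in neigh_b) or (
            other.b in neigh_a and other.a in neigh_b
        ):
            return True
    return False


def confirm_all(
    pairs: Set[OrthologPair], registry: Registry, window_k: int = 5
) -> Set[OrthologPair]:
    """Context-confirm every pair against the full pair set."""
    # Index neighbourhood protein sets once; pair lookup by member.
    by_protein: Dict[str, Set[OrthologPair]] = {}
    for p in pairs:
        by_protein.setdefault(p.a, set()).add(p)
        by_protein.setdefault(p.b, set()).add(p)
    confirmed: Set[OrthologPair] = set()
    for pair in pairs:
        gene_a = registry.gene_for_protein(pair.a)
        gene_b = registry.gene_for_protein(pair.b)
        neigh_a = {
            registry.genes[g].product_protein
            for g in registry.neighbor_genes(gene_a.id, window_k)
        }
        neigh_b = {
            registry.genes[g].product_protein
            for g in registry.neighbor_genes(gene_b.id, window_k)
        }
        candidates = set()
        for prot in neigh_a | neigh_b:
            candidates |= by_protein.get(prot, set())
        ok = False
        for other in candidates:
            if other.members == pair.members:
                continue
            if (other.a in neigh_a and other.b in neigh_b) or (
                other.b in neigh_a and other.a in neigh_b
            ):
                ok = True
                break
        if ok:
            confirmed.add(
                OrthologPair(pair.a, pair.b, context_confirmed=True)
            )
    return confirmed


@dataclass
class ReductaseInstance:
    """One called copy of a reductase in a genome: the catalytic protein
    plus the operon co-members matched to the entry's other subunits."""

    genome_id: str
    entry: str
    catalytic_protein: str
    members: Dict[str, Set[str]] = field(default_factory=dict)  # role -> proteins

    def proteins(self) -> Set[str]:
        out = {self.catalytic_protein}
        for group in self.members.values():
            out |= group
        return out


@dataclass
class ReductaseCalls:
    """Presence/copy-number matrix plus the per-copy instances."""

    matrix: pd.DataFrame  # genomes x entries, integer copy numbers
    instances: List[ReductaseInstance]

    def presence(self, genome_id: str, entry: str) -> bool:
        return bool(self.matrix.at[genome_id, entry] > 0)

    def presence_row(self, genome_id: str) -> Dict[str, int]:
        return {k: int(v) for k, v in self.matrix.loc[genome_id].items()}


def _protein_matches_subunit(
    protein_id: str,
    subunit: Subunit,
    registry: Registry,
    partner_of: Mapping[str, Dict[str, str]],
) -> bool:
    """A protein matches a subunit reference by confirmed orthology, by
    sharing a domain family with the reference protein, or (for bare
    accession references) by carrying the referenced family."""
    ref = subunit.reference
    if ref in registry.proteins:
        if partner_of.get(protein_id, {}).get(ref) is not None:
            return True
        return bool(
            registry.proteins[ref].domain_families
            & registry.proteins[protein_id].domain_families
        )
    return ref in registry.proteins[protein_id].domain_families


def call_reductases(
    registry: Registry,
    ortholog_pairs: Set[OrthologPair],
    catalog: Optional[Mapping[str, ReductaseCatalogEntry]] = None,
    require_context: bool = True,
    params: Optional[ScreenParams] = None,
    similarity: Optional[SimilarityTable] = None,
) -> ReductaseCalls:
    """Genome x reductase copy-number matrix from ortholog pairs.

    An entry is present in a genome iff at least one of its catalytic
    subunit references has a (context-confirmed, unless relaxed) ortholog
    there.  Once presence is established, the copy number counts
    non-identical catalytic homologs: strict best-bidirectional hits can
    only ever name one partner per genome, so additional copies are the
    genome's other proteins whose similarity to the catalytic reference
    passes the orthology cutoff (when a similarity table is supplied).
    Accessory subunits never create presence; they are recorded per copy
    for the complex-composition audit.
    """
    catalog = catalog if catalog is not None else registry.catalog
    params = params or ScreenParams()
    usable = {
        p
        for p in ortholog_pairs
        if p.context_confirmed or not require_context
    }
    # protein -> {partner protein: pair} across usable pairs
    partner_of: Dict[str, Dict[str, str]] = {}
    for pair in usable:
        partner_of.setdefault(pair.a, {})[pair.b] = pair.b
        partner_of.setdefault(pair.b, {})[pair.a] = pair.a

    # cutoff-passing homologs of each reference protein (either direction)
    homologs_of: Dict[str, Set[str]] = {}
    if similarity is not None:
        df = similarity.frame
        ok = df[df["evalue"] <= params.ortholog_evalue_cutoff]
        for row in ok.itertuples(index=False):
            if row.query in registry.proteins and row.subject in registry.proteins:
                homologs_of.setdefault(row.subject, set()).add(row.query)
                homologs_of.setdefault(row.query, set()).add(row.subject)

    genome_ids = sorted(registry.genomes)
    entry_names = sorted(catalog)
    matrix = pd.DataFrame(0, index=genome_ids, columns=entry_names, dtype=int)
    instances: List[ReductaseInstance] = []

    from .screen import predict_operons  # local import to avoid a cycle

    operon_of: Dict[str, List[str]] = {}
    operons_done: Set[str] = set()

    def operon_members(gene_id: str, genome_id: str) -> List[str]:
        if genome_id not in operons_done:
            for op in predict_operons(registry, genome_id, params.operon_max_gap_bp):
                for g in op.genes:
                    operon_of[g] = list(op.genes)
            operons_done.add(genome_id)
        return operon_of.get(gene_id, [gene_id])

    def build_instance(entry, entry_name, genome_id, copy_protein):
        members: Dict[str, Set[str]] = {}
        op_genes = operon_members(
            registry.gene_for_protein(copy_protein).id, genome_id
        )
        co_proteins = {
            registry.genes[g].product_protein
            for g in op_genes
            if registry.genes[g].product_protein != copy_protein
        }
        for sub in entry.accessory_subunits:
            hits = {
                p
                for p in co_proteins
                if _protein_matches_subunit(p, sub, registry, partner_of)
            }
            if hits:
                members.setdefault(sub.role.value, set()).update(hits)
        return ReductaseInstance(
            genome_id=genome_id,
            entry=entry_name,
            catalytic_protein=copy_protein,
            members=members,
        )

    for entry_name in entry_names:
        entry = catalog[entry_name]
        cat_refs = [r for r in entry.catalytic_references if r in registry.proteins]
        for ref in cat_refs:
            ref_genome = registry.genome_of_protein(ref)
            anchors = [
                p
                for p in sorted(partner_of.get(ref, {}))
                if registry.genome_of_protein(p) != ref_genome
            ]
            genomes_present = sorted(
                {registry.genome_of_protein(p) for p in anchors}
            )
            for genome_id in genomes_present:
                copies = {
                    p for p in anchors if registry.genome_of_protein(p) == genome_id
                }
                # paralog expansion within a presence-confirmed genome
                for hom in homologs_of.get(ref, set()):
                    if registry.genome_of_protein(hom) == genome_id:
                        copies.add(hom)
                for copy_protein in sorted(copies):
                    instances.append(
                        build_instance(entry, entry_name, genome_id, copy_protein)
                    )
    # copy number: non-identical catalytic homologs per genome/entry
    seen: Set[Tuple[str, str, str]] = set()
    for inst in instances:
        key = (inst.genome_id, inst.entry, inst.catalytic_protein)
        if key not in seen:
            seen.add(key)
            matrix.at[inst.genome_id, inst.entry] += 1
    return ReductaseCalls(matrix=matrix, instances=instances)
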