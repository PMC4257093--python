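"""Readers and writers for the pipeline's on-disk formats.

A fixture directory holds everything one analysis needs:

* ``genomes.tsv`` — genome_id, taxon, status, length_bp
* ``genes.gff3`` — gene coordinates/strand (1-based inclusive); each
  feature carries ``ID``, ``protein_id`` and ``genome_id`` attributes
* ``domains.tsv`` — protein_id, family (one row per assignment)
* ``localization.tsv`` — protein_id, signal_peptide, tm_segments,
  compartment
* ``similarity.tsv`` — query, subject, bitscore, evalue
* ``catalog.yaml`` — the reductase catalog
* ``metadata_labels.tsv`` — genome_id, source, label (external lifestyle
  labels)
* ``relatedness.tsv`` — genome_a, genome_b, identity (16S)
* ``essential_families.txt`` — one accession per line
* ``family/`` — tree.nwk, alignment.fasta, known.tsv, context.tsv for
  the catalytic-subunit family analysis
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import load_catalog
from .completeness import RelatednessProvider
from .model import (
    Compartment,
    Gene,
    Genome,
    Protein,
    Registry,
    RegistryError,
    Status,
)
from .orthologs import SimilarityTable


def write_gff3(registry: Registry, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome_id in sorted(registry.genomes):
            genome = registry.genomes[genome_id]
            for contig in genome.contigs:
                for gid in registry.genes_on_contig(genome_id, contig):
                    gene = registry.genes[gid]
                    attrs = (
                        f"ID={gene.id};protein_id={gene.product_protein};"
                        f"genome_id={gene.genome_id}"
                    )
                    fh.write(
                        f"{gene.contig}\tgutresp\tgene\t{gene.start}\t"
                        f"{gene.end}\t.\t{gene.strand}\t.\t{attrs}\n"
                    )


def read_gff3(path) -> List[Gene]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: List[Gene] = []
    for feat in db.all_features():
        if feat.featuretype != "gene":
            continue
        genes.append(
            Gene(
                id=feat.attributes["ID"][0],
                genome_id=feat.attributes["genome_id"][0],
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product_protein=feat.attributes["protein_id"][0],
            )
        )
    return genes


def load_registry(
    annotation_file,
    genomes_table,
    domain_table,
    localization_table,
    catalog_config=None,
) -> Registry:
    """Build a cross-linked registry from the input files.

    Validation problems (unresolvable gene->protein links, domain or
    localization rows naming missing proteins, membrane proteins without
    TM segments) are aggregated into one :class:`RegistryError` listing
    every offender.
    """
    registry = Registry()
    problems: List[str] = []

    genomes_df = pd.read_csv(genomes_table, sep="\t")
    for row in genomes_df.itertuples(index=False):
        registry.add_genome(
            Genome(
                id=str(row.genome_id),
                taxon=str(row.taxon),
                status=Status(row.status),
                length_bp=int(row.length_bp),
            )
        )

    genes = read_gff3(annotation_file)

    loc_df = pd.read_csv(localization_table, sep="\t")
    loc: Dict[str, tuple] = {}
    for i, row in enumerate(loc_df.itertuples(index=False)):
        loc[str(row.protein_id)] = (
            bool(int(row.signal_peptide)),
            int(row.tm_segments),
            Compartment(row.compartment),
        )

    dom_df = pd.read_csv(domain_table, sep="\t")
    domains: Dict[str, Set[str]] = {}
    for row in dom_df.itertuples(index=False):
        domains.setdefault(str(row.protein_id), set()).add(str(row.family))

    known_proteins = {g.product_protein for g in genes}
    for i, row in enumerate(dom_df.itertuples(index=False)):
        if str(row.protein_id) not in known_proteins:
            problems.append(
                f"domain table row {i}: unknown protein {row.protein_id!r} "
                f"(family {row.family})"
            )
    for pid in loc:
        if pid not in known_proteins:
            problems.append(
                f"localization table: unknown protein {pid!r}"
            )

    for gene in genes:
        if gene.genome_id not in registry.genomes:
            problems.append(f"gene {gene.id}: unknown genome {gene.genome_id}")
            continue
        pid = gene.product_protein
        sp, tm, comp = loc.get(pid, (False, 0, Compartment.UNKNOWN))
        protein = Protein(
            id=pid,
            gene_id=gene.id,
            domain_families=domains.get(pid, set()),
            signal_peptide=sp,
            tm_segments=tm,
            compartment=comp,
        )
        registry.add_gene(gene, protein)

    if catalog_config is not None:
        registry.catalog = load_catalog(catalog_config)

    if problems:
        raise RegistryError(problems)
    registry.validate()
    return registry


def write_registry_tables(registry: Registry, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "genome_id": g.id,
                "taxon": g.taxon,
                "status": g.status.value,
                "length_bp": g.length_bp,
            }
            for g in registry.genomes.values()
        ]
    ).to_csv(outdir / "genomes.tsv", sep="\t", index=False)
    write_gff3(registry, outdir / "genes.gff3")
    dom_rows = [
        {"protein_id": p.id, "family": fam}
        for p in registry.proteins.values()
        for fam in sorted(p.domain_families)
    ]
    pd.DataFrame(dom_rows, columns=["protein_id", "family"]).to_csv(
        outdir / "domains.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "protein_id": p.id,
                "signal_peptide": int(p.signal_peptide),
                "tm_segments": p.tm_segments,
                "compartment": p.compartment.value,
            }
            for p in registry.proteins.values()
        ]
    ).to_csv(outdir / "localization.tsv", sep="\t", index=False)


def load_fixture_dir(path) -> Registry:
    """Load a registry from a fixture directory written by
    :func:`write_registry_tables` (plus ``catalog.yaml`` if present)."""
    path = Path(path)
    catalog = path / "catalog.yaml"
    return load_registry(
        annotation_file=path / "genes.gff3",
        genomes_table=path / "genomes.tsv",
        domain_table=path / "domains.tsv",
        localization_table=path / "localization.tsv",
        catalog_config=catalog if catalog.exists() else None,
    )


def read_similarity(path) -> SimilarityTable:
    df = pd.read_csv(path, sep="\t")
    return SimilarityTable(df)


def read_metadata_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_relatedness(path) -> RelatednessProvider:
    return RelatednessProvider.from_table(pd.read_csv(path, sep="\t"))


def read_essential_families(path) -> Set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_essential_families(families, path) -> None:
    with open(path, "w") as fh:
        for fam in sorted(families):
            fh.write(fam + "\n")


def write_alignment(alignment: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in alignment.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }
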