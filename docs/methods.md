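# Methods

`gutresp` reconstructs the respiratory capacity of a panel of gut
microbial genomes from annotation-level inputs: gene coordinates,
protein domain-family assignments, localization features (signal
peptide, transmembrane segments), pairwise protein similarity scores,
a protein-family tree with alignment, and a catalog of reductase types.
This note describes the models and rules each stage implements, the
parameters that matter, what the synthetic panels emulate, and the
choices made where the design was genuinely open.

## Genome completeness

Draft assemblies blur the meaning of gene absence: a reductase may be
missing from the organism or merely from the assembly. Two approaches
are implemented.

* **Essential-gene fraction** — the share of a user-supplied list of
  essential domain families with at least one member protein in the
  genome. It is reported as a diagnostic only: even finished genomes
  can score well below 1.0 against a generic list (the panel plants a
  finished genome at the minimum), so no threshold separates complete
  from incomplete and the fraction never drives the verdict.
* **Length comparison** (adopted) — a draft is *probably complete* iff
  its length is at least the length of one closely related finished
  genome, else *incomplete*. Relatives are chosen by tier: same
  species, else same genus, else the finished genome(s) of maximal 16S
  identity, all ties included (a conservative widening of the
  comparison set). A draft with no relatives at any tier is
  *unassessable*. Ties in length count as complete: equality carries no
  evidence of truncation.

Finished genomes are *complete* by definition. Downstream, "reliable"
means complete or probably complete; only in reliable genomes are gene
absences treated as evidence.

## Reductase calls: best bidirectional hits with genomic context

Orthology is called per genome pair from a BLAST-tabular similarity
table. Protein `a`'s best subject in genome B (highest bitscore; ties
broken toward the lexicographically smallest subject id, for
determinism under input permutation) must be `b`, and vice versa, with
both directions passing the orthology e-value cutoff (default 1e-20
equivalent; a separate permissive 1e-10 tier is reserved for family
enumeration and never creates presence calls). A BBH pair is
*context-confirmed* when at least one additional BBH pair links genes
within ±5 genes of both members (window configurable; truncated at
contig edges). Context confirmation is required for presence by
default — the classic defence against stray best hits — with a flag to
relax it.

A catalog entry is *present* in a genome when one of its catalytic
subunit references has a context-confirmed ortholog there. Strict BBH
can name at most one partner per genome, so the **copy number** counts
non-identical catalytic homologs: once presence is established, every
additional protein of that genome whose similarity to the catalytic
reference passes the orthology cutoff is a copy. Accessory subunits
(membrane anchor, electron transfer, maturation) never create
presence; they are matched within the copy's predicted operon — by
confirmed orthology, by shared domain family with the reference
protein, or by carrying a bare accession reference — and feed the
composition audit.

## Family specificity: clade propagation and SDP classification

The catalytic subunits of many anaerobic reductases belong to one
molybdopterin-oxidoreductase family; the subunit determines the
substrate, so labelling family members labels reductases.

**Clade propagation.** On a rooted tree (unrooted input is rejected
with an instruction to midpoint-root; the loader midpoint-roots
automatically), the traversal finds maximal clades in which (a) every
experimentally known tip carries the same specificity and (b) the
tips' genomic-context signatures pairwise share at least one
neighbouring family accession. Unknown tips of such clades inherit the
specificity (method `phylogeny`). Known labels are never overwritten;
clades mixing specificities propagate nothing, though their qualifying
subclades still do. "Conserved context" is quantified as the pairwise
shared-accession rule because no numeric definition exists in the
literature the catalog derives from.

**SDP classification.** Members outside qualifying clades are scored
against specificity-determining positions. Candidate columns are
gap-filtered (a column is dropped if any group exceeds 50% gaps — the
`sdp_max_gap_fraction` parameter), then ranked by the mutual
information between column residue and group label over non-gap
entries. Significance is assessed against a column-shuffle null
(group labels permuted within the column; default 100 permutations):
columns with z ≥ 3 are retained. Group profiles are Laplace-smoothed
residue log-frequencies over the 20 amino acids. An unknown sequence
is assigned the group with maximal summed log-frequency over the SDP
columns where it is ungapped, provided the margin over the runner-up
reaches 2 natural-log units; otherwise it stays `unknown`. A sequence
gapped at every SDP column is never assigned. The margin makes toy
models with one or two weak columns abstain by construction — an
intended property, not a defect.

The exact statistic of dedicated SDP software is not re-derived; the
gap-filtered MI + permutation-z classifier is this package's own.

## Candidate screens

* **Operons** are maximal runs of same-strand, same-contig genes with
  intergenic gaps ≤ 300 bp (configurable). The threshold is a standard
  prokaryotic operon proxy; nothing downstream is sensitive to ±100 bp.
* **Filter cascade** (novel microaerobic reductase pattern): stage 1
  keeps proteins whose domain families intersect a user-supplied
  keyword set (e.g. flavin/thiol-binding families); stage 2 keeps
  exported proteins (signal peptide or ≥1 TM segment); stage 3 keeps
  those whose operon contains a distinct partner protein from an
  oxygen/thiol-binding family (default AhpC/TSA, PF00578). The trace
  records membership at every stage; stages are nested by
  construction.
* **Cross-strain co-occurrence**: an operon survives iff every strain
  of a panel has some operon containing a BBH partner for each of its
  genes. The empty panel keeps everything (vacuous universal).
* **Orphan-accessory scan** (novel thiosulfate-reductase pattern): an
  operon is flagged when it carries ≥2 accessory-subunit homologs of
  one catalog entry, no catalytic subunit of that entry, and at least
  one protein from a plausible alternative catalytic family (default:
  c-type cytochromes, PF02335). The ≥2 threshold keeps single stray
  homologs from implying a complex.

## Oxygen-lifestyle classification and consistency

Reliable genomes: any aerobic-category reductase → *aerophilic*; else
any microaerobic → *microaerophilic*, flagged a *strong microaerobe*
when no anaerobic reductase is present; else *anaerobic*. Incomplete
genomes get hedged classes (*aerophilic* is still definite since it
rests on a presence; absences yield *at least microaerophilic* / *most
likely anaerobic*). The strong flag is never set for incomplete
genomes: the absence it encodes is not trustworthy there. Entries with
category `none` (transporters, assimilatory enzymes, catalog-extended
hydrogenases) never affect the class. Unset completeness is refused.

Predictions are scored against external label sets through an explicit
vocabulary map (shipped as a default, overridable): aerophilic ↔
{aerobe, facultative}; the microaerophilic classes ↔ {microaerophile,
facultative, nanaerobe}; the anaerobic classes ↔ {anaerobe, obligate
anaerobe}. Unmapped labels (e.g. "aerotolerant") count as
inconsistent-with-warning, so vocabulary gaps are visible rather than
silently scored. Genomes are partitioned by label availability (both /
metadata-only / assertion-only / none); per-group consistent counts
and round-half-up percentages are reported plus pooled metadata
consistency.

## Complex-composition audit

Respiratory complexes are modular: the same catalytic subunit pairs
with varying anchors and carriers across genomes. Each called copy is
audited against its entry's subunit roster. Predicted localization is
membrane if any member has a TM segment, extracellular if export is by
signal peptide only, cytoplasmic otherwise. A copy whose catalytic
subunit is present but whose membrane-anchor roles are all absent is a
*soluble variant* — unless a genome-wide search finds anchor homologs
outside the copy's operon, in which case the flag downgrades to
*distally encoded* (anchors can be encoded far from the catalytic
gene). Copies of one entry within a genome that diverge in
localization (one membrane-associated, one cytoplasmic) are reported
as candidate assimilatory duplicates. The audit annotates only; it
never alters presence calls, and whether soluble variants are truly
assimilatory is left open.

## Nitrogen-oxide profiles and exchange networks

Catalog entries carry pathway-step tags over the fixed step set
NO3→NO2, NO2→NH3, NO2→NO, NO→N2O, N2O→N2, plus a transporter tag, and
a respiratory/assimilatory mode. Route completeness uses respiratory
steps only: *complete ammonification* = NO3→NO2 ∧ NO2→NH3; *complete
denitrification* = all four denitrifying steps; *partial* = some but
not all of either route; *none* otherwise.

Exchange edges (producer, metabolite, consumer) are inferred for
nitrite and nitric oxide (nitrous oxide behind a flag, default off,
since the evidence for that handoff is weaker): the producer performs
the respiratory step generating the metabolite and cannot consume it
by any route — assimilatory consumption also disqualifies imports, but
assimilatory production never makes a producer, since it is
cytoplasmic biosynthetic flux, not secreted respiratory product; the
consumer performs a respiratory consuming step and cannot produce the
metabolite respiratorily. Both ends must be co-habitation eligible:
both in the microaerobic-capable class set or both in the anaerobic
set (configurable). Producer eligibility requires only the immediately
upstream step, not the full route from nitrate.

## Synthetic panels

The generators plant every fixture with exact counts, so calibrated
marginals are regression-testable rather than stochastic; randomness
(seeded throughout) affects only lengths, jitter, noise hits and
emission noise.

The default `PanelSpec` encodes the study conditions of a 254-genome
gut reference panel: 55 finished / 149 probably complete / 50
incomplete; among the 204 reliable genomes 25 aerophilic (one without
microaerobic reductases), 92 microaerophilic (27 strong), 87
anaerobic; incomplete genomes 4/19/27; prevalences Cyd 126, Cyf 14
(5 genomes carry both), Frd 93, Nrf 55, Nar 36, Nap 27, Dms 23 with
one 12-copy carrier; a nitrogen-route mix of 28 complete ammonifiers,
1 denitrifier and 44 partial genomes (8 nitrate-only with the
antiporter, 5 Nap-only, 27 nitrite-only, 1 nitrate→NO, 3 with the
skipped NO2→NO step); label availability 98/136/5/15 with 42 and 14
planted inconsistencies. These printed marginals are not all jointly
attainable (their own sums disagree in places), so the calibration
keeps the class counts and the headline prevalences exact and derives
a consistent decomposition for the rest; `PanelSpec.validate`
rejects any edit that breaks joint feasibility, with an explanation.

Structurally, each genome carries housekeeping and essential-family
genes plus one operon per planted reductase copy, orthologous to a
reference genome holding every catalog subunit; similarity tables give
planted orthologs bitscores strictly above a sub-cutoff noise floor,
and e-values derive monotonically from bitscores. Single-subunit
operons gain a conserved anchor neighbour so genuine orthologs can be
context-confirmed. What the panels deliberately do **not** emulate:
sequence evolution (similarity is synthesized, not aligned), realistic
genome architecture beyond ordering and spacing, annotation error in
the input tables, and HGT-style context shuffling. Green tests
therefore certify the inference rules and their implementations, not
robustness to noisy real-world annotation.

The cascade fixture plants the candidate-screen counts
(187 keyword families, 42 with hits, 75 candidates, 7 exported, 3 in
partnered operons, 2 of 3 operons shared by all five strains); the
family fixture plants monophyletic specificity clades (100 tips, 8
groups, 25% known tips, ≥2 known per clade) with per-clade context
accessions, plus detached members in a mixed clade that only the SDP
route can recover, and 10 SDP columns at 5% emission noise over a
60-column alignment.

## Numerical conventions and degenerate inputs

* Reported percentages use round-half-up at the stated precision
  (`decimal`-based, so 51.97% at one decimal is 52.0). Percentages over
  a k-part partition can deviate from 100 by up to 0.05k after
  rounding; tests bound accordingly.
* Coordinates are 1-based inclusive everywhere (GFF convention);
  intergenic gap between adjacent genes is `next.start − prev.end − 1`.
* Similarity tables keep the best HSP per ordered pair (bitscore, then
  smaller e-value); all tie-breaks are lexicographic for determinism.
* Empty inputs are contracts, not crashes: empty keyword set → empty
  trace; empty strain panel → all operons kept; no finished genomes →
  unassessable; an SDP model whose columns are all gap-filtered is
  flagged empty and classifies nothing.

## Problem sizes

The default test-and-acceptance configuration analyzes the 254-genome
panel (~15k genes), one 5-strain cascade fixture, and 100-tip family
fixtures (20 seeds for the recovery suite; 5 in the acceptance
script); the randomized invariant sweep runs 200 seeds of reduced
fixtures. These sizes keep the whole suite near ten seconds while
leaving every marginal of the study conditions intact.

## Known limitations

* Presence requires context confirmation uniformly; whether the
  original procedure demanded it for unambiguous calls too is unknown,
  hence the relax flag.
* The SDP classifier is a stand-alone statistic, deliberately simpler
  than dedicated SDP software; its z-threshold and margin are
  conservative defaults, exposed as parameters.
* Exchange inference is qualitative — no flux, thermodynamics or
  spatial modelling; co-habitation is a class-level gate, not an
  oxygen-gradient model.
* The literature-derived lifestyle comparison is reproduced only as an
  accounting exercise over label tables; no genus-level literature
  mapping is attempted.
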