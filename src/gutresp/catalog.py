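"""Reductase catalog: the controlled list of respiratory reductase types.

The catalog is an editable configuration (YAML) seeded here with the
well-characterised terminal reductases of gut bacteria.  Each entry names
its oxygen category (aerobic / microaerobic / anaerobic, or ``none`` for
transporters and assimilatory enzymes that never drive lifestyle
classification), its substrate, and a subunit roster.  Subunit references
are either reference-protein ids (resolved by orthology) or domain-family
accessions (resolved by domain content); users extend the catalog by
editing the YAML.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import yaml

from .model import Category, ReductaseCatalogEntry, Subunit, SubunitRole

# Families treated as plausible alternative catalytic subunits in the
# orphan-accessory-operon scan (c-type cytochromes, cf. cytochrome c-552/4).
DEFAULT_ALT_CATALYTIC_FAMILIES = frozenset({"PF02335"})

# Oxygen/thiol-binding partner families for the microaerobic-reductase
# candidate screen (AhpC/TSA peroxiredoxins).
DEFAULT_PARTNER_FAMILIES = frozenset({"PF00578"})


def _entry(
    name: str,
    category: str,
    substrate: str,
    subunits: Iterable[tuple],
    pathway_step: Optional[str] = None,
    mode: str = "respiratory",
) -> ReductaseCatalogEntry:
    return ReductaseCatalogEntry(
        name=name,
        category=Category(category),
        substrate=substrate,
        subunits=[Subunit(SubunitRole(r), ref) for r, ref in subunits],
        pathway_step=pathway_step,
        mode=mode,
    )


def default_catalog() -> Dict[str, ReductaseCatalogEntry]:
    """Catalog seeded with the named reductase types of the human gut set."""
    entries = [
        # -- aerobic terminal oxidases (heme-copper family, PF00115) ------
        _entry("Cyo", "aerobic", "oxygen",
               [("catalytic", "REF_CYOB"), ("membrane_anchor", "REF_CYOA"),
                ("electron_transfer", "REF_CYOC")]),
        _entry("Qox", "aerobic", "oxygen",
               [("catalytic", "REF_QOXB"), ("membrane_anchor", "REF_QOXA")]),
        _entry("Cta", "aerobic", "oxygen",
               [("catalytic", "REF_CTAD"), ("membrane_anchor", "REF_CTAC")]),
        _entry("Cco", "aerobic", "oxygen",
               [("catalytic", "REF_CCON"), ("membrane_anchor", "REF_CCOO")]),
        # -- microaerobic (high-affinity) oxidases -------------------------
        _entry("Cyd", "microaerobic", "oxygen",
               [("catalytic", "REF_CYDA"), ("membrane_anchor", "REF_CYDB")]),
        _entry("Cyf", "microaerobic", "oxygen",
               [("catalytic", "REF_CYFA"), ("membrane_anchor", "REF_CYFB"),
                ("electron_transfer", "REF_CYFE"),
                ("electron_transfer", "REF_CYFF")]),
        # -- anaerobic reductases -----------------------------------------
        _entry("Frd", "anaerobic", "fumarate",
               [("catalytic", "REF_FRDA"), ("electron_transfer", "REF_FRDB"),
                ("membrane_anchor", "REF_FRDC")]),
        _entry("Nar", "anaerobic", "nitrate",
               [("catalytic", "REF_NARG"), ("electron_transfer", "REF_NARH"),
                ("membrane_anchor", "REF_NARI")],
               pathway_step="NO3->NO2"),
        _entry("Nap", "anaerobic", "nitrate",
               [("catalytic", "REF_NAPA"), ("electron_transfer", "REF_NAPB")],
               pathway_step="NO3->NO2"),
        _entry("Nrf", "anaerobic", "nitrite",
               [("catalytic", "REF_NRFA"), ("electron_transfer", "REF_NRFB"),
                ("electron_transfer", "REF_NRFC"),
                ("membrane_anchor", "REF_NRFD")],
               pathway_step="NO2->NH3"),
        _entry("Nir", "anaerobic", "nitrite",
               [("catalytic", "REF_NIRK")], pathway_step="NO2->NO"),
        _entry("Nor", "anaerobic", "nitric oxide",
               [("catalytic", "REF_NORB"), ("membrane_anchor", "REF_NORC")],
               pathway_step="NO->N2O"),
        _entry("Nos", "anaerobic", "nitrous oxide",
               [("catalytic", "REF_NOSZ"), ("maturation", "PF05048"),
                ("maturation", "PF05573"), ("maturation", "PF00005"),
                ("membrane_anchor", "PF05140")],
               pathway_step="N2O->N2"),
        _entry("Dms", "anaerobic", "DMSO/TMAO",
               [("catalytic", "REF_DMSA"), ("electron_transfer", "REF_DMSB"),
                ("membrane_anchor", "REF_DMSC")]),
        _entry("Tor", "anaerobic", "TMAO",
               [("catalytic", "REF_TORA"), ("membrane_anchor", "REF_TORC")]),
        _entry("Ttr", "anaerobic", "tetrathionate",
               [("catalytic", "REF_TTRA"), ("electron_transfer", "REF_TTRB"),
                ("membrane_anchor", "REF_TTRC")]),
        _entry("Phs", "anaerobic", "thiosulfate",
               [("catalytic", "REF_PHSA"), ("electron_transfer", "REF_PHSB"),
                ("membrane_anchor", "REF_PHSC")]),
        _entry("Tsr", "anaerobic", "thiosulfate",
               [("catalytic", "REF_TSRA"), ("maturation", "REF_TSRD"),
                ("electron_transfer", "REF_TSRE"),
                ("membrane_anchor", "REF_TSRF")]),
        _entry("Ynf", "anaerobic", "selenate",
               [("catalytic", "REF_YNFE"), ("electron_transfer", "REF_YNFG"),
                ("membrane_anchor", "REF_YNFH")]),
        _entry("Asr", "anaerobic", "sulfite",
               [("catalytic", "REF_ASRA"), ("electron_transfer", "REF_ASRB"),
                ("membrane_anchor", "REF_ASRC")]),
        _entry("Apr", "anaerobic", "adenylyl sulfate",
               [("catalytic", "REF_APRA"), ("electron_transfer", "REF_APRB")]),
        _entry("Hdr", "anaerobic", "heterodisulfide",
               [("catalytic", "REF_HDRA"), ("electron_transfer", "REF_HDRB")]),
        _entry("Arr", "anaerobic", "arsenate",
               [("catalytic", "REF_ARRA"), ("electron_transfer", "REF_ARRB")]),
        # -- assimilatory enzymes and transporters (no oxygen category) ----
        _entry("NirBD", "none", "nitrite",
               [("catalytic", "REF_NIRB"), ("electron_transfer", "REF_NIRD")],
               pathway_step="NO2->NH3", mode="assimilatory"),
        _entry("NasBA", "none", "nitrate",
               [("catalytic", "REF_NASA"), ("electron_transfer", "REF_NASB")],
               pathway_step="NO3->NO2", mode="assimilatory"),
        _entry("NarK", "none", "nitrate/nitrite antiport",
               [("catalytic", "REF_NARK")], pathway_step="transporter"),
    ]
    return {e.name: e for e in entries}


def load_catalog(path) -> Dict[str, ReductaseCatalogEntry]:
    """Read a catalog from YAML; invalid categories or entries without a
    catalytic subunit are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries: Dict[str, ReductaseCatalogEntry] = {}
    for rec in doc.get("entries", []):
        try:
            category = Category(rec["category"])
        except ValueError as exc:
            raise ValueError(
                f"catalog entry {rec.get('name')}: unknown category "
                f"{rec.get('category')!r}"
            ) from exc
        entry = ReductaseCatalogEntry(
            name=rec["name"],
            category=category,
            substrate=rec.get("substrate", ""),
            subunits=[
                Subunit(SubunitRole(s["role"]), s["reference"])
                for s in rec.get("subunits", [])
            ],
            pathway_step=rec.get("pathway_step"),
            mode=rec.get("mode", "respiratory"),
        )
        entries[entry.name] = entry
    return entries


def dump_catalog(catalog: Dict[str, ReductaseCatalogEntry], path) -> None:
    doc = {
        "entries": [
            {
                "name": e.name,
                "category": e.category.value,
                "substrate": e.substrate,
                "pathway_step": e.pathway_step,
                "mode": e.mode,
                "subunits": [
                    {"role": s.role.value, "reference": s.reference}
                    for s in e.subunits
                ],
            }
            for e in catalog.values()
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
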