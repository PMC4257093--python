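"""Oxygen-lifestyle classification and consistency scoring.

A genome's class follows from which oxygen categories of reductase it
carries, qualified by assembly completeness: absences are only trusted in
finished / probably complete genomes.  Predictions are scored against
external label sets (database metadata vs pathway-assertion calls)
through an explicit vocabulary mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .model import (
    Category,
    Completeness,
    OxygenClass,
    OxygenClassValue,
    ReductaseCatalogEntry,
)
from .rounding import percent

# Default mapping from predicted class to acceptable external labels.
# Labels are compared lower-case; anything unmapped counts as
# inconsistent-with-warning.
DEFAULT_LABEL_MAP: Dict[OxygenClassValue, Set[str]] = {
    OxygenClassValue.AEROPHILIC: {"aerobe", "facultative", "facultative aerobe"},
    OxygenClassValue.MICROAEROPHILIC: {
        "microaerophile", "facultative", "facultative aerobe", "nanaerobe",
    },
    OxygenClassValue.AT_LEAST_MICROAEROPHILIC: {
        "microaerophile", "facultative", "facultative aerobe", "nanaerobe",
    },
    OxygenClassValue.ANAEROBIC: {"anaerobe", "obligate anaerobe"},
    OxygenClassValue.MOST_LIKELY_ANAEROBIC: {"anaerobe", "obligate anaerobe"},
}

KNOWN_LABELS: Set[str] = set().union(*DEFAULT_LABEL_MAP.values()) | {
    "aerotolerant", "microaerophilic", "aerobic", "anaerobic",
}


def classify_oxygen(
    presence_row: Mapping[str, int],
    catalog: Mapping[str, ReductaseCatalogEntry],
    completeness: Completeness,
) -> OxygenClass:
    """Lifestyle class from the reductase complement.

    Reliable (complete / probably complete) genomes: aerobic reductase ->
    aerophilic; else microaerobic -> microaerophilic (a strong
    microaerobe when no anaerobic reductase is present); else anaerobic.
    Incomplete genomes get the hedged classes since absences may be
    assembly gaps.  Unset completeness is refused.
    """
    if completeness is Completeness.UNSET:
        raise ValueError("cannot classify a genome with unset completeness")
    have: Set[Category] = set()
    for name, copies in presence_row.items():
        if copies > 0 and name in catalog:
            have.add(catalog[name].category)
    reliable = completeness in (
        Completeness.COMPLETE,
        Completeness.PROBABLY_COMPLETE,
    )
    if Category.AEROBIC in have:
        return OxygenClass(OxygenClassValue.AEROPHILIC)
    if Category.MICROAEROBIC in have:
        if reliable:
            # strong microaerobe: trusted absence of anaerobic reductases
            return OxygenClass(
                OxygenClassValue.MICROAEROPHILIC,
                strong_microaerobe=Category.ANAEROBIC not in have,
            )
        # incomplete assembly: absence of anaerobic reductases is not
        # evidence, so the strong flag is never set
        return OxygenClass(OxygenClassValue.AT_LEAST_MICROAEROPHILIC)
    if reliable:
        return OxygenClass(OxygenClassValue.ANAEROBIC)
    return OxygenClass(OxygenClassValue.MOST_LIKELY_ANAEROBIC)


def reconcile_label(
    pred: OxygenClass,
    external_label: str,
    label_map: Optional[Mapping[OxygenClassValue, Set[str]]] = None,
) -> Tuple[str, bool]:
    """Compare a prediction with an external label.

    Returns (verdict, warned): verdict is "consistent" or "inconsistent";
    warned is True when the label has no mapping for any class (so the
    inconsistency is a vocabulary gap, not a disagreement).
    """
    label_map = label_map or DEFAULT_LABEL_MAP
    label = external_label.strip().lower()
    mapped_anywhere = any(label in v for v in label_map.values())
    if label in label_map.get(pred.value, set()):
        return "consistent", False
    return "inconsistent", not mapped_anywhere


@dataclass
class GroupConsistency:
    n: int = 0
    consistent: int = 0

    @property
    def inconsistent(self) -> int:
        return self.n - self.consistent

    def percentages(self, ndigits: int = 1) -> Dict[str, float]:
        return {
            "consistent_pct": percent(self.consistent, self.n, ndigits),
            "inconsistent_pct": percent(self.inconsistent, self.n, ndigits),
        }


@dataclass
class ConsistencyReport:
    """Per-availability-group consistency against external label sets."""

    group_sizes: Dict[str, int] = field(default_factory=dict)
    metadata: Dict[str, GroupConsistency] = field(default_factory=dict)
    assertion: Dict[str, GroupConsistency] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    rejected: List[str] = field(default_factory=list)

    def pooled_metadata(self) -> GroupConsistency:
        pooled = GroupConsistency()
        for gc in self.metadata.values():
            pooled.n += gc.n
            pooled.consistent += gc.consistent
        return pooled

    def to_dict(self) -> Dict[str, object]:
        pooled = self.pooled_metadata()
        return {
            "group_sizes": dict(self.group_sizes),
            "metadata": {
                g: {"n": gc.n, "consistent": gc.consistent, **gc.percentages()}
                for g, gc in self.metadata.items()
            },
            "assertion": {
                g: {"n": gc.n, "consistent": gc.consistent, **gc.percentages()}
                for g, gc in self.assertion.items()
            },
            "pooled_metadata": {
                "n": pooled.n,
                "consistent": pooled.consistent,
                **pooled.percentages(),
            },
            "warnings": list(self.warnings),
            "rejected": list(self.rejected),
        }


def consistency_report(
    predictions: Mapping[str, OxygenClass],
    label_table: pd.DataFrame,
    label_map: Optional[Mapping[OxygenClassValue, Set[str]]] = None,
) -> ConsistencyReport:
    """Score predictions against a label table (genome_id, source, label).

    Genomes are partitioned by label availability into groups "both",
    "metadata_only", "assertion_only" and "none"; consistency counts and
    round-half-up percentages are reported per group, plus pooled
    metadata consistency across every group possessing metadata.  Rows
    whose source is outside {metadata, assertion} are rejected and
    logged, not fatal.
    """
    label_map = label_map or DEFAULT_LABEL_MAP
    report = ConsistencyReport()
    labels: Dict[str, Dict[str, str]] = {}
    for row in label_table.itertuples(index=False):
        source = str(row.source).strip().lower()
        if source not in ("metadata", "assertion"):
            report.rejected.append(
                f"{row.genome_id}: unknown label source {row.source!r}"
            )
            continue
        labels.setdefault(str(row.genome_id), {})[source] = str(row.label)

    groups: Dict[str, List[str]] = {
        "both": [], "metadata_only": [], "assertion_only": [], "none": [],
    }
    for genome_id in predictions:
        have = labels.get(genome_id, {})
        if "metadata" in have and "assertion" in have:
            groups["both"].append(genome_id)
        elif "metadata" in have:
            groups["metadata_only"].append(genome_id)
        elif "assertion" in have:
            groups["assertion_only"].append(genome_id)
        else:
            groups["none"].append(genome_id)
    report.group_sizes = {g: len(ids) for g, ids in groups.items()}

    for group in ("both", "metadata_only"):
        gc = GroupConsistency()
        for genome_id in groups[group]:
            verdict, warned = reconcile_label(
                predictions[genome_id], labels[genome_id]["metadata"], label_map
            )
            gc.n += 1
            if verdict == "consistent":
                gc.consistent += 1
            if warned:
                report.warnings.append(
                    f"{genome_id}: unmapped label "
                    f"{labels[genome_id]['metadata']!r}"
                )
        report.metadata[group] = gc
    for group in ("both", "assertion_only"):
        gc = GroupConsistency()
        for genome_id in groups[group]:
            verdict, warned = reconcile_label(
                predictions[genome_id], labels[genome_id]["assertion"], label_map
            )
            gc.n += 1
            if verdict == "consistent":
                gc.consistent += 1
            if warned:
                report.warnings.append(
                    f"{genome_id}: unmapped label "
                    f"{labels[genome_id]['assertion']!r}"
                )
        report.assertion[group] = gc
    return report


def class_counts(
    predictions: Mapping[str, OxygenClass],
) -> Dict[str, int]:
    """Counts per class value, plus the strong-microaerobe subcount."""
    counts = {v.value: 0 for v in OxygenClassValue}
    strong = 0
    for oc in predictions.values():
        counts[oc.value.value] += 1
        if oc.strong_microaerobe:
            strong += 1
    counts["strong_microaerobe"] = strong
    return counts
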