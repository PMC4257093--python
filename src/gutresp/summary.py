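"""Summary reporting: the subsystem sheet and headline statistics.

The subsystem matrix is the genome x reductase copy-number sheet; the
summary report aggregates per-reductase genome counts and percentages
(denominator: all genomes in the registry), oxygen-class counts,
per-genome reductase totals and specificity-method counts, all rounded
half-up at the requested precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import pandas as pd

from .model import OxygenClass, Registry, SpecificityAssignment, PathwayProfile
from .oxygen import class_counts
from .rounding import percent
from .specificity import summarize_assignments


def write_subsystem_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_subsystem_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="genome_id")
    df.index.name = None  # in-memory matrices carry an anonymous index
    return df


@dataclass
class SummaryReport:
    n_genomes: int
    reductase_counts: Dict[str, int]
    reductase_percent: Dict[str, float]
    class_counts: Dict[str, int]
    per_genome_totals: Dict[str, int]
    method_counts: Dict[str, int] = field(default_factory=dict)
    pathway_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_genomes": self.n_genomes,
            "reductase_counts": dict(self.reductase_counts),
            "reductase_percent": dict(self.reductase_percent),
            "class_counts": dict(self.class_counts),
            "per_genome_totals": dict(self.per_genome_totals),
            "method_counts": dict(self.method_counts),
            "pathway_counts": dict(self.pathway_counts),
        }


def summarize(
    registry: Registry,
    matrix: pd.DataFrame,
    assignments: Optional[Mapping[str, SpecificityAssignment]] = None,
    classes: Optional[Mapping[str, OxygenClass]] = None,
    profiles: Optional[Mapping[str, PathwayProfile]] = None,
    ndigits: int = 1,
) -> SummaryReport:
    """Aggregate the pipeline's outputs into one report.

    Presence counts a genome once per reductase type regardless of copy
    number; per-genome totals sum copy numbers (multi-copy reductases
    count each non-identical copy).  Percentages use the rows of
    ``matrix`` as their denominator, so pass the matrix restricted to the
    genomes under study.
    """
    n = int(matrix.shape[0])
    counts = {
        name: int((matrix[name] > 0).sum()) for name in matrix.columns
    }
    pcts = {name: percent(c, n, ndigits) for name, c in counts.items()}
    totals = {gid: int(matrix.loc[gid].sum()) for gid in matrix.index}
    report = SummaryReport(
        n_genomes=n,
        reductase_counts=counts,
        reductase_percent=pcts,
        class_counts=class_counts(classes) if classes else {},
        per_genome_totals=totals,
    )
    if assignments:
        report.method_counts = summarize_assignments(assignments)["counts"]
    if profiles:
        from .nitrogen import pathway_summary

        report.pathway_counts = pathway_summary(profiles)["counts"]
    return report
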