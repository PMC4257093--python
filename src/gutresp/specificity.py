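"""Substrate-specificity assignment for a catalytic-subunit protein family.

The molybdopterin-oxidoreductase catalytic subunits determine what an
anaerobic reductase reduces, so labelling family members labels the
reductase.  Two complementary routes are implemented:

1. *Clade propagation*: on a rooted family tree, the specificity of
   experimentally known members is extrapolated to every member of a
   maximal clade whose known tips agree on one specificity and whose tips
   share conserved genomic context (pairwise, at least one common
   neighbour family).
2. *SDP classification*: for members outside such clades, alignment
   columns that discriminate the specificity groups
   (specificity-determining positions) are selected by gap-filtered
   mutual information against a column-shuffle null, and unknowns are
   assigned to the group with the best summed log-frequency score,
   subject to a margin over the runner-up.

Known labels are never overwritten, and clades mixing specificities
propagate nothing.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .model import AssignmentMethod, SpecificityAssignment

GAP_CHARS = frozenset("-.")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FamilyTree:
    """Rooted family tree with per-tip known specificity and genomic
    context signature (set of neighbouring domain-family accessions)."""

    tree: dendropy.Tree
    known: Dict[str, str] = field(default_factory=dict)  # tip -> specificity
    contexts: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [t.label for t in self.tree.taxon_namespace]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels are not unique")

    @property
    def tips(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def load_family_tree(
    path,
    known: Optional[Mapping[str, str]] = None,
    contexts: Optional[Mapping[str, Iterable[str]]] = None,
    midpoint_root: bool = True,
) -> FamilyTree:
    """Read a newick tree; unrooted trees are midpoint-rooted by default."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if not tree.is_rooted and midpoint_root:
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.is_rooted = True
    return FamilyTree(
        tree=tree,
        known=dict(known or {}),
        contexts={k: set(v) for k, v in (contexts or {}).items()},
    )


def _pairwise_context_conserved(
    tips: Sequence[str], contexts: Mapping[str, Set[str]]
) -> bool:
    for i, a in enumerate(tips):
        ca = contexts.get(a, set())
        for b in tips[i + 1 :]:
            if not (ca & contexts.get(b, set())):
                return False
    return True


def propagate_by_clade(
    family: FamilyTree,
    existing: Optional[Mapping[str, SpecificityAssignment]] = None,
) -> Dict[str, SpecificityAssignment]:
    """Propagate known specificities through maximal qualifying clades.

    A clade qualifies when it contains at least one known tip, all its
    known tips share one specificity, and its tips' context signatures
    pairwise share at least one accession.  Unknown tips of a qualifying
    clade receive the shared specificity (method=phylogeny); traversal
    does not descend into qualifying clades, making them maximal.
    """
    if not family.tree.is_rooted:
        raise ValueError(
            "unrooted tree: midpoint-root it first "
            "(load_family_tree performs this automatically)"
        )
    if not family.known:
        raise ValueError("propagation requires at least one known tip")
    assignments: Dict[str, SpecificityAssignment] = dict(existing or {})
    for tip, spec in family.known.items():
        assignments[tip] = SpecificityAssignment(tip, spec, AssignmentMethod.KNOWN)

    def visit(node) -> None:
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        known_specs = {family.known[t] for t in tips if t in family.known}
        if len(known_specs) == 1 and _pairwise_context_conserved(
            tips, family.contexts
        ):
            spec = known_specs.pop()
            for t in tips:
                if t not in family.known:
                    assignments[t] = SpecificityAssignment(
                        t, spec, AssignmentMethod.PHYLOGENY
                    )
            return  # maximal clade: do not descend
        for child in node.child_nodes():
            visit(child)

    visit(family.tree.seed_node)
    return assignments


@dataclass
class SDPModel:
    """Selected specificity-determining columns and per-group residue
    log-frequency profiles (Laplace-smoothed over the 20 amino acids)."""

    columns: List[int]
    groups: List[str]
    log_profiles: Dict[str, Dict[int, Dict[str, float]]]
    scores: Dict[int, float] = field(default_factory=dict)
    z_scores: Dict[int, float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.columns


def _column_mi(residues: Sequence[str], labels: Sequence[str]) -> float:
    """Mutual information between residue and group label over non-gap
    entries of one alignment column (natural log)."""
    pairs = [
        (r, g) for r, g in zip(residues, labels) if r not in GAP_CHARS
    ]
    n = len(pairs)
    if n == 0:
        return 0.0
    joint = Counter(pairs)
    res_marg = Counter(r for r, _ in pairs)
    grp_marg = Counter(g for _, g in pairs)
    mi = 0.0
    for (r, g), c in joint.items():
        p = c / n
        mi += p * math.log(p * n * n / (res_marg[r] * grp_marg[g]))
    return mi


def fit_sdp(
    alignment: Mapping[str, str],
    grouped_known: Mapping[str, str],
    max_gap_fraction: float = 0.5,
    z_threshold: float = 3.0,
    n_permutations: int = 100,
    seed: int = 0,
) -> SDPModel:
    """Select SDP columns by gap-filtered mutual information.

    Columns where any group exceeds ``max_gap_fraction`` gaps are
    excluded outright.  Remaining columns are kept when their observed
    residue/group mutual information stands ``z_threshold`` standard
    deviations above a null obtained by shuffling group labels within the
    column.  Requires >=2 groups with >=2 sequences each.
    """
    members: Dict[str, List[str]] = {}
    for pid, grp in grouped_known.items():
        if pid in alignment:
            members.setdefault(grp, []).append(pid)
    groups = sorted(members)
    if len(groups) < 2 or any(len(members[g]) < 2 for g in groups):
        raise ValueError("SDP fitting needs >=2 groups with >=2 sequences each")
    ids = [pid for g in groups for pid in sorted(members[g])]
    labels = [grouped_known[pid] for pid in ids]
    seqs = [alignment[pid] for pid in ids]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment sequences have unequal lengths")

    rng = np.random.default_rng(seed)
    label_arr = np.array(labels)
    kept: List[int] = []
    scores: Dict[int, float] = {}
    z_scores: Dict[int, float] = {}
    for col in range(length):
        residues = [s[col] for s in seqs]
        gap_ok = True
        for g in groups:
            rs = [r for r, lab in zip(residues, labels) if lab == g]
            if sum(r in GAP_CHARS for r in rs) / len(rs) > max_gap_fraction:
                gap_ok = False
                break
        if not gap_ok:
            continue
        obs = _column_mi(residues, labels)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = _column_mi(residues, rng.permutation(label_arr))
        mu, sd = float(null.mean()), float(null.std())
        if sd == 0.0:
            z = math.inf if obs > mu else 0.0
        else:
            z = (obs - mu) / sd
        scores[col] = obs
        z_scores[col] = z
        if z >= z_threshold:
            kept.append(col)

    log_profiles: Dict[str, Dict[int, Dict[str, float]]] = {}
    for g in groups:
        prof: Dict[int, Dict[str, float]] = {}
        gseqs = [alignment[pid] for pid in sorted(members[g])]
        for col in kept:
            counts = Counter(
                s[col] for s in gseqs if s[col] not in GAP_CHARS
            )
            total = sum(counts.values()) + len(AMINO_ACIDS)
            prof[col] = {
                aa: math.log((counts.get(aa, 0) + 1) / total)
                for aa in AMINO_ACIDS
            }
        log_profiles[g] = prof
    return SDPModel(
        columns=kept,
        groups=groups,
        log_profiles=log_profiles,
        scores=scores,
        z_scores=z_scores,
    )


def classify_by_sdp(
    model: SDPModel,
    sequence: str,
    margin_threshold: float = 2.0,
) -> Optional[str]:
    """Assign the best-scoring group when its summed log-frequency margin
    over the runner-up reaches ``margin_threshold``; otherwise None.
    A sequence gapped at every SDP column is never assigned."""
    if model.empty:
        return None
    usable = [
        c for c in model.columns if sequence[c] not in GAP_CHARS
    ]
    if not usable:
        return None
    totals: Dict[str, float] = {}
    for g in model.groups:
        prof = model.log_profiles[g]
        totals[g] = sum(
            prof[c].get(sequence[c], math.log(1e-6)) for c in usable
        )
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        return ranked[0][0]
    best, runner = ranked[0], ranked[1]
    if best[1] - runner[1] >= margin_threshold:
        return best[0]
    return None


def assign_specificities(
    family: FamilyTree,
    alignment: Mapping[str, str],
    max_gap_fraction: float = 0.5,
    z_threshold: float = 3.0,
    margin_threshold: float = 2.0,
    n_permutations: int = 100,
    seed: int = 0,
) -> Dict[str, SpecificityAssignment]:
    """Full pipeline: known labels, clade propagation, then SDP for the
    remainder; anything still unlabelled is recorded as unassigned."""
    assignments = propagate_by_clade(family)
    grouped = {
        pid: a.specificity
        for pid, a in assignments.items()
        if a.method in (AssignmentMethod.KNOWN, AssignmentMethod.PHYLOGENY)
    }
    remaining = [t for t in family.tips if t not in assignments]
    model: Optional[SDPModel] = None
    members_per_group = Counter(grouped.values())
    if remaining and len(members_per_group) >= 2 and all(
        v >= 2 for v in members_per_group.values()
    ):
        model = fit_sdp(
            alignment,
            grouped,
            max_gap_fraction=max_gap_fraction,
            z_threshold=z_threshold,
            n_permutations=n_permutations,
            seed=seed,
        )
    for tip in remaining:
        spec = None
        if model is not None and tip in alignment:
            spec = classify_by_sdp(model, alignment[tip], margin_threshold)
        if spec is None:
            assignments[tip] = SpecificityAssignment(
                tip, "unknown", AssignmentMethod.UNASSIGNED
            )
        else:
            assignments[tip] = SpecificityAssignment(
                tip, spec, AssignmentMethod.SDP
            )
    return assignments


def summarize_assignments(
    assignments: Mapping[str, SpecificityAssignment],
) -> Dict[str, object]:
    """Counts per assignment method plus the list of unassigned proteins."""
    counts = {m.value: 0 for m in AssignmentMethod}
    unassigned: List[str] = []
    for pid, a in assignments.items():
        counts[a.method.value] += 1
        if a.method is AssignmentMethod.UNASSIGNED:
            unassigned.append(pid)
    return {"counts": counts, "unassigned": sorted(unassigned)}
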