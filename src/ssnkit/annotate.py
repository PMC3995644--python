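"""Annotation overlays for representative nodes.

A representative node aggregates its member sequences' metadata under three
rules: a class or taxonomy label is shown only when strictly more than 50% of
the *annotated* members carry it (boundary ties yield no label); a reaction
type is shown when *any* member has experimental evidence for it, with the
evidence source tracked as this_work / literature / both; and taxonomy
categories are matched against lineages in a fixed precedence order from most
specific (Insecta) to superkingdoms (Eukaryota, Bacteria, Archaea).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .records import InputError

__all__ = [
    "AnnotationRecord",
    "NodeOverlay",
    "DEFAULT_REACTION_TYPES",
    "TAXONOMY_PRECEDENCE",
    "majority_label",
    "any_evidence_reactions",
    "taxonomy_category",
    "node_taxonomy",
    "length_histogram",
    "overlay_node",
]

#: Controlled vocabulary of reaction-type categories (extensible).
DEFAULT_REACTION_TYPES = frozenset({
    "DSBR",        # disulfide bond reductase
    "ERO",         # epoxide ring opening
    "NA",          # nucleophilic addition
    "NAS",         # nucleophilic aromatic substitution
    "NS",          # nucleophilic substitution
    "RD",          # reductive dehalogenase
    "peroxidase",
    "isomerase",
    "DHAR",        # dehydroascorbate reductase
    "other",
})

_EVIDENCE_SOURCES = ("this_work", "literature")

#: Most specific category first: class Insecta, then kingdoms, superkingdoms.
TAXONOMY_PRECEDENCE = (
    "Insecta", "Metazoa", "Viridiplantae", "Fungi",
    "Eukaryota", "Bacteria", "Archaea",
)


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-sequence metadata as read from the annotation table."""

    sequence_id: str
    class_label: str | None = None
    taxonomy_lineage: tuple = ()
    reaction_evidence: frozenset = frozenset()  # of (reaction_type, source)
    structure_ids: frozenset = frozenset()      # of (structure_id, source)

    def __post_init__(self) -> None:
        for rtype, source in self.reaction_evidence:
            if source not in _EVIDENCE_SOURCES:
                raise InputError(
                    f"unknown evidence source {source!r} for {self.sequence_id!r}"
                )
            _ = rtype  # validated against the vocabulary at overlay time


@dataclass(frozen=True)
class NodeOverlay:
    """Aggregated annotation attributes of one representative node."""

    node_id: str
    class_label: str | None = None
    taxonomy_category: str | None = None
    reaction_types: frozenset = frozenset()
    reaction_summary: str = "none"  # none | single | multiple
    evidence_source: str = "none"   # none | this_work | literature | both
    structure_flag: str = "none"    # none | this_work | literature | both


def majority_label(labels) -> str | None:
    """Strict >50% majority over annotated members; None when no majority.

    Unannotated members (None) are excluded from the denominator; a node
    whose annotated members split exactly 50/50 gets no label.
    """
    annotated = [lab for lab in labels if lab is not None]
    if not annotated:
        return None
    label, count = Counter(annotated).most_common(1)[0]
    return label if count * 2 > len(annotated) else None


def _source_flag(sources) -> str:
    sources = set(sources)
    if not sources:
        return "none"
    if sources == {"this_work"}:
        return "this_work"
    if sources == {"literature"}:
        return "literature"
    return "both"


def any_evidence_reactions(member_evidence, vocabulary=DEFAULT_REACTION_TYPES):
    """Union of member reaction evidence with summary and source flag.

    ``member_evidence`` is an iterable over members, each a set of
    ``(reaction_type, source)`` tuples.  Returns ``(reaction set, summary,
    source flag)`` where summary is none/single/multiple ("multiple" when two
    or more distinct types occur in the node).
    """
    types, sources = set(), set()
    for evidence in member_evidence:
        for rtype, source in evidence:
            if rtype not in vocabulary:
                raise InputError(
                    f"unknown reaction type {rtype!r}; valid: {sorted(vocabulary)}"
                )
            types.add(rtype)
            sources.add(source)
    summary = "none" if not types else ("single" if len(types) == 1 else "multiple")
    return frozenset(types), summary, _source_flag(sources)


def taxonomy_category(lineage) -> str | None:
    """First matching type-of-life category in precedence order.

    ``lineage`` is an ordered rank->name list (or "; "-joined string).  The
    precedence runs most-specific first, so a metazoan lineage containing
    Insecta is categorized Insecta, not Metazoa or Eukaryota.
    """
    if lineage is None:
        return None
    if isinstance(lineage, str):
        names = {part.strip() for part in lineage.split(";")}
    else:
        names = set(lineage)
    for category in TAXONOMY_PRECEDENCE:
        if category in names:
            return category
    return None


def node_taxonomy(member_lineages) -> str | None:
    """Majority type-of-life category over a node's annotated members."""
    return majority_label(taxonomy_category(lin) for lin in member_lineages)


@dataclass(frozen=True)
class LengthHistogram:
    counts: tuple
    bin_edges: tuple
    range_fractions: dict = field(default_factory=dict)
    n: int = 0


def length_histogram(sequences, bin_width: int = 10, ranges=()) -> LengthHistogram | None:
    """Histogram of full-length sequence lengths plus named-range fractions.

    ``ranges`` is an iterable of inclusive ``(lo, hi)`` bounds; the returned
    ``range_fractions`` maps each to the fraction of sequences inside it.
    Returns None for empty input.
    """
    if bin_width < 1:
        raise InputError("bin_width must be >= 1")
    lengths = np.array([len(s) for s in sequences])
    if lengths.size == 0:
        return None
    lo = (int(lengths.min()) // bin_width) * bin_width
    hi = int(lengths.max()) + bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    fractions = {
        (rlo, rhi): float(((lengths >= rlo) & (lengths <= rhi)).mean())
        for rlo, rhi in ranges
    }
    return LengthHistogram(counts=tuple(int(c) for c in counts),
                           bin_edges=tuple(int(e) for e in edges),
                           range_fractions=fractions, n=int(lengths.size))


def overlay_node(node_id: str, member_annotations,
                 vocabulary=DEFAULT_REACTION_TYPES) -> NodeOverlay:
    """Apply all three aggregation rules to one node's member annotations."""
    members = list(member_annotations)
    class_label = majority_label(m.class_label for m in members)
    tax = node_taxonomy(m.taxonomy_lineage or None for m in members)
    reactions, summary, evidence_source = any_evidence_reactions(
        (m.reaction_evidence for m in members), vocabulary=vocabulary
    )
    structure_flag = _source_flag(
        src for m in members for _sid, src in m.structure_ids
    )
    return NodeOverlay(
        node_id=node_id, class_label=class_label, taxonomy_category=tax,
        reaction_types=reactions, reaction_summary=summary,
        evidence_source=evidence_source, structure_flag=structure_flag,
    )
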