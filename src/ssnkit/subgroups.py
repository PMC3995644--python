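"""E-value thresholding, connected components, and hierarchical subgroups.

Level 1 subgroups are connected components of the representative network at a
permissive E-value cutoff (1e-13 by default); level 2 subgroups are
components at a stricter cutoff (1e-25), named under their level 1 parent
("Main.1"-style).  At both levels a component is designated a subgroup only
when it carries at least ``min_members`` member *sequences* (counted after
expanding representative nodes to their identity-cluster members, 50 by
default); smaller components are recorded as unassigned clusters or
singletons.  Member sequences inherit the subgroup of their representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .networks import SimilarityNetwork
from .records import InputError

__all__ = [
    "SubgroupAssignment",
    "SubgroupingResult",
    "apply_threshold",
    "connected_components",
    "designate_subgroups",
    "propagate_members",
]


class ConsistencyError(InputError):
    """A stricter-cutoff component spans two parent subgroups."""


@dataclass(frozen=True)
class SubgroupAssignment:
    """One designated subgroup (or unassigned cluster when name is None)."""

    level: int
    name: str | None
    node_ids: tuple
    member_sequence_ids: tuple
    is_singleton: bool
    parent: str | None = None

    @property
    def member_count(self) -> int:
        return len(self.member_sequence_ids)


@dataclass
class SubgroupingResult:
    level: int
    cutoff: float
    min_members: int
    subgroups: tuple
    unassigned: tuple  # components below min_members (incl. singleton nodes)

    @property
    def node_to_name(self) -> dict:
        out = {}
        for sg in self.subgroups:
            for node in sg.node_ids:
                out[node] = sg.name
        for sg in self.unassigned:
            for node in sg.node_ids:
                out[node] = None
        return out

    def __iter__(self):
        return iter(self.subgroups)


def _edge_keeps(score_kind: str, value: float, cutoff: float) -> bool:
    # E-values: lower is more significant, keep when <= cutoff.
    # SN scores: higher is more similar, keep when >= cutoff.
    return value >= cutoff if score_kind == "sn" else value <= cutoff


def apply_threshold(net: SimilarityNetwork, cutoff: float) -> SimilarityNetwork:
    """Monotone re-thresholding: same nodes, edges passing ``cutoff`` kept.

    The input network is not modified.
    """
    if net.score_kind == "evalue" and cutoff <= 0:
        raise InputError("E-value cutoff must be positive")
    attr = "sn_score" if net.score_kind == "sn" else "e_value"
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for u, v, d in net.graph.edges(data=True):
        if _edge_keeps(net.score_kind, d[attr], cutoff):
            g.add_edge(u, v, **d)
    return SimilarityNetwork(
        graph=g, node_kind=net.node_kind, score_kind=net.score_kind,
        active_threshold=cutoff, clusters=dict(net.clusters),
    )


def connected_components(net: SimilarityNetwork):
    """Undirected connected components; isolated nodes are singletons.

    Deterministic order: components sorted by (-size, smallest node id).
    """
    comps = [tuple(sorted(c)) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _component_members(net: SimilarityNetwork, comp) -> tuple:
    members = []
    for node in comp:
        if node in net.clusters:
            members.extend(net.clusters[node].member_ids)
        else:
            members.append(node)
    return tuple(members)


def designate_subgroups(net: SimilarityNetwork, cutoff: float,
                        min_members: int = 50, level: int = 1,
                        parent_assignment: SubgroupingResult | None = None,
                        label_map: dict | None = None) -> SubgroupingResult:
    """Threshold, take components, and name those with enough members.

    Level 1 components are auto-named "G1", "G2", ... by descending member
    count unless ``label_map`` supplies a curated name for one of a
    component's nodes.  Level 2 components are named "<parent>.<k>" with k by
    descending member count within each parent; they must lie entirely inside
    one level 1 subgroup (guaranteed when the level 2 cutoff is stricter),
    and components whose nodes were unassigned at level 1 stay unassigned.
    """
    if level not in (1, 2):
        raise InputError(f"level must be 1 or 2, got {level}")
    if level == 2 and parent_assignment is None:
        raise InputError("level 2 designation requires the level 1 assignment")
    if min_members < 1:
        raise InputError("min_members must be >= 1")

    thresholded = apply_threshold(net, cutoff)
    comps = connected_components(thresholded)
    annotated = []  # (member_count, comp, members, parent_name)
    parent_lookup = parent_assignment.node_to_name if parent_assignment else {}
    for comp in comps:
        members = _component_members(net, comp)
        parent = None
        if level == 2:
            parents = {parent_lookup.get(node) for node in comp}
            named = {p for p in parents if p is not None}
            if len(named) > 1:
                raise ConsistencyError(
                    f"component {comp[:3]}... spans level 1 subgroups {sorted(named)}"
                )
            if None in parents and named:
                raise ConsistencyError(
                    f"component {comp[:3]}... mixes assigned and unassigned "
                    "level 1 nodes"
                )
            parent = next(iter(named)) if named else None
        annotated.append((len(members), comp, members, parent))

    # Descending member count, ties by smallest node id (stable auto-naming).
    annotated.sort(key=lambda t: (-t[0], t[1][0]))

    subgroups, unassigned = [], []
    auto_index = 0
    per_parent_index: dict = {}
    for count, comp, members, parent in annotated:
        qualifies = count >= min_members and (level == 1 or parent is not None)
        if not qualifies:
            unassigned.append(
                SubgroupAssignment(level=level, name=None, node_ids=comp,
                                   member_sequence_ids=members,
                                   is_singleton=len(comp) == 1, parent=parent)
            )
            continue
        if level == 1:
            curated = None
            if label_map:
                hits = {label_map[n] for n in comp if n in label_map}
                if len(hits) > 1:
                    raise InputError(
                        f"label_map assigns multiple names {sorted(hits)} to one component"
                    )
                curated = next(iter(hits)) if hits else None
            auto_index += 1
            name = curated if curated is not None else f"G{auto_index}"
        else:
            k = per_parent_index.get(parent, 0) + 1
            per_parent_index[parent] = k
            name = f"{parent}.{k}"
        subgroups.append(
            SubgroupAssignment(level=level, name=name, node_ids=comp,
                               member_sequence_ids=members,
                               is_singleton=len(comp) == 1, parent=parent)
        )
    return SubgroupingResult(level=level, cutoff=cutoff, min_members=min_members,
                             subgroups=tuple(subgroups), unassigned=tuple(unassigned))


def propagate_members(assignment: SubgroupingResult, clusters) -> dict:
    """Per-sequence subgroup labels: members inherit their representative's.

    ``clusters`` is the iterable of RepClusters behind the network's nodes.
    Returns ``{sequence_id: subgroup name or None}``; unassigned
    representatives propagate None.
    """
    by_rep = {cl.representative_id: cl for cl in clusters}
    node_names = assignment.node_to_name
    missing = [n for n in node_names if n not in by_rep]
    if missing:
        raise InputError(
            f"representative nodes without a cluster: {sorted(missing)[:5]}"
        )
    labels = {}
    for rep, name in node_names.items():
        for mid in by_rep[rep].member_ids:
            labels[mid] = name
    return labels
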