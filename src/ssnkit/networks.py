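"""Representative (identity-filtered) and full similarity networks.

A full network has one node per sequence and one edge per reported pair.  A
representative network compacts it: sequences are first partitioned by greedy
incremental identity clustering (ID50 by default) with one representative per
cluster, and an edge between two representative nodes carries the *least
significant* (numerically largest) E-value among all reported member pairs
spanning the two clusters — so an edge certifies even the weakest member
relationship.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import PairSimilarity
from .records import InputError, check_unique_ids

__all__ = [
    "RepCluster",
    "SimilarityNetwork",
    "greedy_identity_cluster",
    "identity_lookup_from_pairs",
    "build_rep_network",
    "build_full_network",
    "edge_median_stats",
]


@dataclass(frozen=True)
class RepCluster:
    """An identity-threshold cluster with one designated representative."""

    representative_id: str
    member_ids: tuple
    identity_threshold: float

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise InputError("cluster must have at least one member")
        if self.representative_id not in self.member_ids:
            raise InputError(
                f"representative {self.representative_id!r} is not a member"
            )

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class SimilarityNetwork:
    """Nodes plus attributed edges with an active similarity threshold.

    ``score_kind`` is ``"evalue"`` (edge kept when e_value <= threshold) or
    ``"sn"`` (structure SN score; edge kept when sn_score >= threshold).
    """

    graph: nx.Graph
    node_kind: str = "sequence"  # or "representative" / "structure"
    score_kind: str = "evalue"
    active_threshold: float | None = None
    clusters: dict = field(default_factory=dict)  # rep id -> RepCluster

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def member_count(self, node_id) -> int:
        """Number of member sequences behind a node (1 for plain sequences)."""
        if node_id in self.clusters:
            return len(self.clusters[node_id])
        return 1


def identity_lookup_from_pairs(pairs, sequences=None):
    """Build a pair-identity source from PairSimilarity records.

    Returns a callable (id_a, id_b) -> identity fraction; unreported pairs
    score 0 (no detectable similarity implies identity below any threshold).

    When ``sequences`` is given, identity is computed over the shorter
    sequence (identities / min length), the convention of greedy identity
    clusterers: a short high-identity local alignment between otherwise
    unrelated proteins then cannot clear a 50% threshold.  Without lengths
    the alignment-length denominator is used.
    """
    table = {p.key(): p for p in pairs}
    lengths = {r.id: len(r) for r in sequences} if sequences is not None else None

    def lookup(id_a: str, id_b: str) -> float:
        p = table.get(frozenset((id_a, id_b)))
        if p is None:
            return 0.0
        if lengths is not None:
            return p.identities / min(lengths[id_a], lengths[id_b])
        return p.identity_fraction

    return lookup


def greedy_identity_cluster(sequences, threshold: float, pair_source):
    """Greedy incremental identity clustering with representative nodes.

    Sequences are processed longest first (ties by identifier); each joins
    the first existing cluster whose representative it matches at >=
    ``threshold`` identity, else founds a new cluster with itself as
    representative.  Because founders are processed in length order the
    representative is always the longest member (ties lexicographic).

    ``pair_source`` is either a callable ``(id_a, id_b) -> identity fraction``
    (see :func:`identity_lookup_from_pairs`) or a Mapping keyed by
    ``frozenset({id_a, id_b})``.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError(f"identity threshold must be in (0, 1], got {threshold}")
    sequences = list(sequences)
    check_unique_ids(sequences)
    if isinstance(pair_source, Mapping):
        table = pair_source

        def identity(x, y):
            v = table.get(frozenset((x, y)), 0.0)
            return v.identity_fraction if isinstance(v, PairSimilarity) else float(v)
    else:
        identity = pair_source

    ordered = sorted(sequences, key=lambda r: (-len(r), r.id))
    reps = []  # representative ids in founding order
    members = {}
    for rec in ordered:
        for rep in reps:
            if identity(rep, rec.id) >= threshold:
                members[rep].append(rec.id)
                break
        else:
            reps.append(rec.id)
            members[rec.id] = [rec.id]
    return [
        RepCluster(representative_id=rep, member_ids=tuple(members[rep]),
                   identity_threshold=threshold)
        for rep in reps
    ]


def build_rep_network(clusters, pairs) -> SimilarityNetwork:
    """Representative network under the least-significant-edge rule.

    One node per cluster.  For each cluster pair the edge E-value is the
    numerically largest E-value among all reported member pairs spanning the
    two clusters, and the edge's percent identity / alignment length are
    taken from that same spanning pair.  Cluster pairs with no reported
    spanning pair get no edge.
    """
    clusters = list(clusters)
    rep_of = {}
    for cl in clusters:
        for mid in cl.member_ids:
            if mid in rep_of:
                raise InputError(f"sequence {mid!r} appears in two clusters")
            rep_of[mid] = cl.representative_id

    g = nx.Graph()
    for cl in clusters:
        g.add_node(cl.representative_id, member_count=len(cl))

    worst = {}  # (rep_a, rep_b) -> PairSimilarity with largest e_value
    for p in pairs:
        if p.id_a not in rep_of or p.id_b not in rep_of:
            raise InputError(
                f"pair ({p.id_a!r}, {p.id_b!r}) references a sequence outside "
                "the clustered universe"
            )
        ra, rb = rep_of[p.id_a], rep_of[p.id_b]
        if ra == rb:
            continue
        key = (ra, rb) if ra <= rb else (rb, ra)
        cur = worst.get(key)
        # Deterministic tie-break on equal E-values: keep the pair with the
        # lexicographically smallest ids.
        if (cur is None or p.e_value > cur.e_value
                or (p.e_value == cur.e_value
                    and (p.id_a, p.id_b) < (cur.id_a, cur.id_b))):
            worst[key] = p
    for (ra, rb), p in worst.items():
        g.add_edge(ra, rb, e_value=p.e_value, percent_identity=p.percent_identity,
                   alignment_length=p.alignment_length,
                   source_pair=(p.id_a, p.id_b))
    return SimilarityNetwork(
        graph=g, node_kind="representative", score_kind="evalue",
        active_threshold=None,
        clusters={cl.representative_id: cl for cl in clusters},
    )


def build_full_network(member_ids, pairs) -> SimilarityNetwork:
    """Full network: one node per sequence, one edge per reported pair."""
    members = set(member_ids)
    g = nx.Graph()
    g.add_nodes_from(sorted(members))
    for p in pairs:
        if p.id_a in members and p.id_b in members:
            g.add_edge(p.id_a, p.id_b, e_value=p.e_value,
                       percent_identity=p.percent_identity,
                       alignment_length=p.alignment_length)
    return SimilarityNetwork(graph=g, node_kind="sequence", score_kind="evalue")


def edge_median_stats(net: SimilarityNetwork):
    """(median percent identity, median alignment length, edge count).

    Medians use the midpoint convention for even-sized edge sets.  Returns
    None for a network with no edges.
    """
    pid = [d["percent_identity"] for _, _, d in net.graph.edges(data=True)]
    if not pid:
        return None
    alen = [d["alignment_length"] for _, _, d in net.graph.edges(data=True)]
    return float(np.median(pid)), float(np.median(alen)), len(pid)
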