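"""Structure similarity networks from pairwise structure-score tables.

Structure chains are deduplicated at 95% sequence identity (ID95) with the
same greedy clustering used for sequence networks, one representative chosen
per cluster by quality (e.g. crystallographic resolution, lower is better).
Edges between representative structures are drawn when the structural
aligner's SN score meets the cutoff (>= 20 by default — note the comparison
direction is opposite to E-values: higher SN means more similar).  Sequence-
derived annotations are transferred to structure nodes through chain-to-
sequence links.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .records import InputError
from .networks import RepCluster, SimilarityNetwork, greedy_identity_cluster

__all__ = [
    "StructureScore",
    "StructureChainRecord",
    "dedupe_chains",
    "build_structure_network",
    "transfer_annotations",
    "read_structure_scores",
    "write_structure_scores",
]


@dataclass(frozen=True)
class StructureScore:
    """One unordered chain pair's structural similarity."""

    chain_id_a: str
    chain_id_b: str
    sn_score: float
    aligned_residues: int

    def __post_init__(self) -> None:
        if self.chain_id_a == self.chain_id_b:
            raise InputError(f"self pair not allowed: {self.chain_id_a!r}")
        if not pd.notna(self.sn_score) or self.sn_score in (float("inf"), float("-inf")):
            raise InputError("sn_score must be finite")


@dataclass(frozen=True)
class StructureChainRecord:
    """A solved structure chain, optionally linked to a dataset sequence."""

    structure_id: str
    sequence: str
    sequence_id: str | None = None
    quality: float | None = None  # e.g. resolution in A; lower is better
    source: str = "literature"    # this_work | literature

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"chain {self.structure_id!r} has an empty sequence")

    @property
    def id(self) -> str:  # duck-types SequenceRecord for clustering
        return self.structure_id

    def __len__(self) -> int:
        return len(self.sequence)


def _exact_identity(chains):
    by_id = {c.structure_id: c for c in chains}

    def identity(id_a: str, id_b: str) -> float:
        a, b = by_id[id_a].sequence, by_id[id_b].sequence
        if len(a) != len(b):
            # Length mismatch: identity over the longer chain.
            short, long_ = sorted((a, b), key=len)
            matches = sum(x == y for x, y in zip(short, long_))
            return matches / len(long_)
        return sum(x == y for x, y in zip(a, b)) / len(a)

    return identity


def dedupe_chains(chains, identity_threshold: float = 0.95, pair_source=None):
    """ID95 deduplication of structure chains with quality-based representatives.

    Reuses greedy identity clustering; within each cluster the representative
    is the member with the best (numerically smallest) quality value, ties by
    identifier; chains without quality metadata rank last.  ``pair_source``
    defaults to exact positional identity, appropriate for duplicate-chain
    removal.
    """
    chains = list(chains)
    if not chains:
        raise InputError("chain set is empty")
    if pair_source is None:
        pair_source = _exact_identity(chains)
    clusters = greedy_identity_cluster(chains, identity_threshold, pair_source)
    by_id = {c.structure_id: c for c in chains}

    def quality_key(chain_id: str):
        q = by_id[chain_id].quality
        return (q is None, q if q is not None else 0.0, chain_id)

    out = []
    for cl in clusters:
        rep = min(cl.member_ids, key=quality_key)
        out.append(RepCluster(representative_id=rep, member_ids=cl.member_ids,
                              identity_threshold=identity_threshold))
    return out


def build_structure_network(representatives, scores, cutoff: float = 20.0
                            ) -> SimilarityNetwork:
    """Structure network: edge iff sn_score >= cutoff between representatives.

    ``representatives`` is an iterable of chain ids (or RepClusters);
    ``scores`` an iterable of StructureScore.  Scores referencing unknown
    chains raise; missing pairs simply get no edge.
    """
    rep_ids = []
    clusters = {}
    for r in representatives:
        if isinstance(r, RepCluster):
            rep_ids.append(r.representative_id)
            clusters[r.representative_id] = r
        else:
            rep_ids.append(r)
    known = set(rep_ids)
    g = nx.Graph()
    g.add_nodes_from(sorted(known))
    for s in scores:
        if s.chain_id_a not in known or s.chain_id_b not in known:
            raise InputError(
                f"score references unknown chain: ({s.chain_id_a!r}, {s.chain_id_b!r})"
            )
        if s.sn_score >= cutoff:
            g.add_edge(s.chain_id_a, s.chain_id_b, sn_score=s.sn_score,
                       aligned_residues=s.aligned_residues,
                       # generic attrs so shared edge statistics work
                       percent_identity=s.sn_score,
                       alignment_length=s.aligned_residues)
    return SimilarityNetwork(graph=g, node_kind="structure", score_kind="sn",
                             active_threshold=cutoff, clusters=clusters)


def transfer_annotations(struct_net: SimilarityNetwork, links: dict,
                         overlays: dict) -> SimilarityNetwork:
    """Copy sequence-derived attributes onto linked structure nodes.

    ``links`` maps chain id -> sequence id (or None); ``overlays`` maps
    sequence id -> attribute dict (subgroup, class, reactions, ...).
    Unlinked chains stay unannotated.  Modifies and returns ``struct_net``.
    """
    for node in struct_net.graph.nodes:
        seq_id = links.get(node)
        if seq_id is None:
            continue
        attrs = overlays.get(seq_id)
        if attrs:
            struct_net.graph.nodes[node].update(attrs)
            struct_net.graph.nodes[node]["sequence_id"] = seq_id
    return struct_net


def read_structure_scores(path):
    """Read a structure-score TSV (chain_a, chain_b, sn_score, aligned_residues)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chain_a", "chain_b", "sn_score", "aligned_residues"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"structure score table missing columns: {sorted(missing)}")
    seen = set()
    out = []
    for r in df.itertuples(index=False):
        key = frozenset((str(r.chain_a), str(r.chain_b)))
        if key in seen:
            raise InputError(f"duplicate structure pair: {sorted(key)}")
        seen.add(key)
        out.append(StructureScore(str(r.chain_a), str(r.chain_b),
                                  float(r.sn_score), int(r.aligned_residues)))
    return out


def write_structure_scores(scores, path) -> None:
    pd.DataFrame(
        [(s.chain_id_a, s.chain_id_b, s.sn_score, s.aligned_residues) for s in scores],
        columns=["chain_a", "chain_b", "sn_score", "aligned_residues"],
    ).to_csv(path, sep="\t", index=False)
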