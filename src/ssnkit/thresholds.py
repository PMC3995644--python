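"""Objective E-value threshold selection.

The representative network is clustered with the Markov Cluster Algorithm
(MCL) at each candidate cutoff, and the cutoff whose connected components
agree best *both* with canonical class labels and with the MCL partition is
selected.  Agreement is measured with the adjusted Rand index (ARI); the
combined score defaults to the mean of the two agreement terms, with ties
broken toward the most stringent cutoff.  The combiner is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .records import InputError
from .networks import SimilarityNetwork
from .subgroups import apply_threshold, connected_components

__all__ = [
    "MCLParams",
    "MCLResult",
    "ThresholdScan",
    "mcl_cluster",
    "adjusted_rand_index",
    "scan_thresholds",
]


@dataclass(frozen=True)
class MCLParams:
    """Markov Cluster Algorithm parameters.

    ``inflation`` (> 1) controls cluster granularity; ``expansion`` is the
    matrix-power step.  Edge weights are derived from the network per
    ``weight_transform``: the default caps -log10(E) at ``cap`` so zero
    E-values stay finite.  Self-loops get each node's maximum incident weight.
    """

    inflation: float = 2.0
    expansion: int = 2
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    weight_transform: str = "neg_log10_evalue_capped"  # | bit_score | binary
    cap: float = 200.0
    prune_below: float = 1e-12

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise InputError("inflation must be > 1")
        if self.expansion < 2:
            raise InputError("expansion must be >= 2")
        if self.convergence_tol <= 0:
            raise InputError("convergence_tol must be positive")


@dataclass
class MCLResult:
    partition: tuple  # of frozensets
    converged: bool
    n_iterations: int
    max_column_sum_error: float  # worst deviation from column-stochasticity

    def labels(self) -> dict:
        return {node: i for i, cluster in enumerate(self.partition) for node in cluster}


def _edge_weight(data: dict, params: MCLParams) -> float:
    if params.weight_transform == "binary":
        return 1.0
    if params.weight_transform == "bit_score":
        return max(float(data.get("bit_score", 1.0)), 0.0)
    ev = float(data["e_value"])
    if ev <= 0.0:
        return params.cap
    return min(-np.log10(ev), params.cap)


def mcl_cluster(net: SimilarityNetwork, params: MCLParams = MCLParams()) -> MCLResult:
    """Markov clustering of a (thresholded, weighted) similarity network.

    Iterates expansion (matrix power), inflation (elementwise power +
    column renormalization) and pruning until the matrix change falls below
    ``convergence_tol``; clusters are read from the attractor structure of
    the limit matrix.  Isolated nodes come out as singletons, and flow can
    never cross between disconnected components.
    """
    nodes = sorted(net.graph.nodes)
    if not nodes:
        raise InputError("cannot cluster an empty network")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, d in net.graph.edges(data=True):
        w = _edge_weight(d, params)
        if w <= 0:
            continue
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    # Self-loops: max incident weight (1.0 for isolated nodes) keeps columns
    # normalizable and damps oscillation.
    for i in range(n):
        peak = m[:, i].max()
        m[i, i] = peak if peak > 0 else 1.0

    m /= m.sum(axis=0, keepdims=True)
    max_col_err = abs(m.sum(axis=0) - 1.0).max()
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = expanded ** params.inflation
        inflated[inflated < params.prune_below] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        new = inflated / colsum
        max_col_err = max(max_col_err, float(abs(new.sum(axis=0) - 1.0).max()))
        change = float(abs(new - m).max())
        m = new
        if change < params.convergence_tol:
            converged = True
            break

    # Attractors are rows with mass on the diagonal; each node joins the
    # cluster of the attractors feeding it. Attractors sharing a node merge.
    tau = 1e-6
    attractors = [i for i in range(n) if m[i, i] > tau]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for j in range(n):
        feeding = [i for i in attractors if m[i, j] > tau]
        for i in feeding[1:]:
            union(feeding[0], i)
    cluster_of = {}
    for j in range(n):
        feeding = [i for i in attractors if m[i, j] > tau]
        if feeding:
            cluster_of[j] = find(feeding[0])
        else:  # numerically starved column: strongest row wins
            cluster_of[j] = find(int(m[:, j].argmax()))
    groups: dict = {}
    for j, root in cluster_of.items():
        groups.setdefault(root, []).append(nodes[j])
    partition = tuple(sorted((frozenset(g) for g in groups.values()),
                             key=lambda s: min(s)))
    return MCLResult(partition=partition, converged=converged, n_iterations=it,
                     max_column_sum_error=max_col_err)


def _as_labels(partition) -> dict:
    """Accept {element: label} mappings or iterables of disjoint sets."""
    if isinstance(partition, dict):
        return dict(partition)
    labels = {}
    for i, group in enumerate(partition):
        for element in group:
            if element in labels:
                raise InputError(f"element {element!r} appears in two blocks")
            labels[element] = i
    return labels


def adjusted_rand_index(p1, p2) -> float:
    """Chance-corrected partition agreement: 1 iff identical, ~0 at random.

    Both arguments may be ``{element: label}`` mappings or iterables of
    disjoint sets over the same element universe.
    """
    l1, l2 = _as_labels(p1), _as_labels(p2)
    if set(l1) != set(l2):
        raise InputError("partitions cover different element universes")
    if not l1:
        raise InputError("partitions are empty")
    elements = sorted(l1)
    a = pd.factorize(np.asarray([l1[e] for e in elements], dtype=object))[0]
    b = pd.factorize(np.asarray([l2[e] for e in elements], dtype=object))[0]
    return float(adjusted_rand_score(a, b))


def _mean_combiner(ari_classes: float, ari_mcl: float) -> float:
    return 0.5 * (ari_classes + ari_mcl)


@dataclass
class ThresholdScan:
    """Per-cutoff agreement table and the selected cutoff."""

    table: pd.DataFrame  # cutoff, n_components, ari_classes, ari_mcl, combined
    selected_cutoff: float

    def row(self, cutoff: float) -> pd.Series:
        return self.table.loc[self.table["cutoff"] == cutoff].iloc[0]


def scan_thresholds(rep_net: SimilarityNetwork, canonical_labels: dict,
                    candidates, mcl_params: MCLParams = MCLParams(),
                    combiner=_mean_combiner) -> ThresholdScan:
    """Score candidate cutoffs by agreement with classes and MCL clusters.

    For each candidate cutoff the network is thresholded and its connected
    components are compared (ARI) against (a) the partition induced by
    ``canonical_labels`` restricted to labeled nodes and (b) the MCL
    partition of the same thresholded, weighted network.  The selected cutoff
    maximizes the combined score; ties go to the most stringent candidate.
    """
    candidates = sorted(set(candidates), reverse=True)  # descending stringency last
    if not candidates:
        raise InputError("at least one candidate cutoff is required")
    labeled = {n: lab for n, lab in canonical_labels.items()
               if lab is not None and n in rep_net.graph}
    if not labeled:
        raise InputError("no labeled nodes: class-agreement term undefined")

    rows = []
    for cutoff in candidates:
        thr = apply_threshold(rep_net, cutoff)
        comps = connected_components(thr)
        comp_labels = _as_labels(comps)
        ari_classes = adjusted_rand_index(
            {n: comp_labels[n] for n in labeled}, labeled
        )
        mcl = mcl_cluster(thr, mcl_params)
        ari_mcl = adjusted_rand_index(comp_labels, mcl.labels())
        rows.append((cutoff, len(comps), ari_classes, ari_mcl,
                     combiner(ari_classes, ari_mcl)))
    table = pd.DataFrame(
        rows, columns=["cutoff", "n_components", "ari_classes", "ari_mcl", "combined"]
    )
    best = table["combined"].max()
    # Ties resolved toward the most stringent (numerically smallest) cutoff.
    selected = float(table.loc[table["combined"] == best, "cutoff"].min())
    return ThresholdScan(table=table, selected_cutoff=selected)
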