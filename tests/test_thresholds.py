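"""Markov clustering, partition agreement, and the threshold scan."""

from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from ssnkit.annotate import majority_label
from ssnkit.networks import SimilarityNetwork
from ssnkit.records import InputError
from ssnkit.thresholds import (
    MCLParams,
    adjusted_rand_index,
    mcl_cluster,
    scan_thresholds,
)


def _net(edges, n_nodes=None, weight_key="e_value", default=1e-20):
    g = nx.Graph()
    if n_nodes:
        g.add_nodes_from(f"n{i}" for i in range(n_nodes))
    for edge in edges:
        u, v = edge[:2]
        e = edge[2] if len(edge) > 2 else default
        g.add_edge(f"n{u}", f"n{v}", **{weight_key: e}, percent_identity=50.0,
                   alignment_length=100)
    return SimilarityNetwork(graph=g, node_kind="representative")


def _pure_python_mcl(adj, inflation=2.0, expansion=2, tol=1e-8, iters=200):
    """Independent fixed-point MCL oracle in plain Python lists."""
    n = len(adj)
    m = [[float(adj[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        peak = max(m[r][i] for r in range(n))
        m[i][i] = peak if peak > 0 else 1.0

    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] /= s
        return mat

    m = normalize(m)
    for _ in range(iters):
        # expansion: matrix power
        powered = m
        for _ in range(expansion - 1):
            powered = [[sum(powered[i][k] * m[k][j] for k in range(n))
                        for j in range(n)] for i in range(n)]
        inflated = normalize([[powered[i][j] ** inflation for j in range(n)]
                              for i in range(n)])
        change = max(abs(inflated[i][j] - m[i][j])
                     for i in range(n) for j in range(n))
        m = inflated
        if change < tol:
            break
    clusters = {}
    for j in range(n):
        attractor = max(range(n), key=lambda i: m[i][j])
        clusters.setdefault(attractor, set()).add(j)
    merged = []
    for group in clusters.values():
        for block in merged:
            if block & group:
                block |= group
                break
        else:
            merged.append(set(group))
    return sorted(tuple(sorted(b)) for b in merged)


class TestMCL:
    def test_disconnected_triangles_never_merge(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        res = mcl_cluster(net)
        assert res.converged
        blocks = sorted(sorted(b) for b in res.partition)
        assert blocks == [["n0", "n1", "n2"], ["n3", "n4", "n5"]]

    def test_single_node_is_singleton(self):
        net = _net([], n_nodes=1)
        res = mcl_cluster(net)
        assert res.partition == (frozenset({"n0"}),)

    def test_output_is_a_partition(self, small_rep_net):
        res = mcl_cluster(small_rep_net)
        nodes = [n for block in res.partition for n in block]
        assert sorted(nodes) == sorted(small_rep_net.graph.nodes)

    def test_column_stochasticity_preserved(self, small_rep_net):
        res = mcl_cluster(small_rep_net)
        assert res.max_column_sum_error < 1e-10

    def test_barbell_split_matches_independent_oracle(self):
        # Two dense 10-cliques joined by one weak edge: inflation 2 must cut
        # the bridge; the oracle is a from-scratch fixed-point iteration.
        n = 20
        g = nx.Graph()
        adj = [[0.0] * n for _ in range(n)]
        for lo in (0, 10):
            for i in range(lo, lo + 10):
                for j in range(i + 1, lo + 10):
                    g.add_edge(f"n{i}", f"n{j}", e_value=1e-30)
                    adj[i][j] = adj[j][i] = 30.0  # -log10(E)
        g.add_edge("n0", "n10", e_value=1e-3)
        adj[0][10] = adj[10][0] = 3.0
        net = SimilarityNetwork(graph=g, node_kind="representative")
        res = mcl_cluster(net)
        got = sorted(sorted(int(x[1:]) for x in block) for block in res.partition)
        want = [sorted(b) for b in _pure_python_mcl(adj)]
        assert got == want == [list(range(10)), list(range(10, 20))]

    def test_invalid_params(self):
        with pytest.raises(InputError):
            MCLParams(inflation=1.0)
        with pytest.raises(InputError):
            mcl_cluster(SimilarityNetwork(graph=nx.Graph()))


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        p = [{"a", "b"}, {"c"}]
        assert adjusted_rand_index(p, p) == 1.0

    def test_symmetry(self):
        p1 = [{"a", "b"}, {"c", "d"}]
        p2 = [{"a"}, {"b", "c"}, {"d"}]
        assert adjusted_rand_index(p1, p2) == adjusted_rand_index(p2, p1)

    def test_crossed_pairs_value(self):
        # Pair-counting contingency is all ones: index 0, expected
        # E = (2*2)/C(4,2) = 2/3, max = 2, so ARI = -(2/3)/(4/3) = -1/2.
        p1 = [{"a", "b"}, {"c", "d"}]
        p2 = [{"a", "c"}, {"b", "d"}]
        expected = Fraction(0 - Fraction(2, 3), 2 - Fraction(2, 3))
        assert adjusted_rand_index(p1, p2) == pytest.approx(float(expected))
        assert float(expected) == -0.5

    def test_universe_mismatch_rejected(self):
        with pytest.raises(InputError):
            adjusted_rand_index([{"a"}], [{"b"}])

    def test_label_mapping_input(self):
        assert adjusted_rand_index({"a": 1, "b": 1, "c": 2},
                                   {"a": "x", "b": "x", "c": "y"}) == 1.0


class TestScanThresholds:
    def test_single_candidate_selected(self, small_rep_net, small_clusters,
                                       small_superfamily):
        _, truth = small_superfamily
        labels = {c.representative_id: truth.family_of(c.representative_id)
                  for c in small_clusters}
        scan = scan_thresholds(small_rep_net, labels, [1e-20])
        assert scan.selected_cutoff == 1e-20

    def test_selected_score_is_argmax(self, small_rep_net, small_clusters,
                                      small_superfamily):
        _, truth = small_superfamily
        labels = {c.representative_id: truth.family_of(c.representative_id)
                  for c in small_clusters}
        cand = [10.0 ** (-k) for k in range(13, 62, 12)]
        scan = scan_thresholds(small_rep_net, labels, cand)
        best = scan.table.loc[scan.table["cutoff"] == scan.selected_cutoff,
                              "combined"].iloc[0]
        assert (scan.table["combined"] <= best + 1e-12).all()

    def test_ties_break_to_most_stringent(self, small_rep_net, small_clusters,
                                          small_superfamily):
        _, truth = small_superfamily
        labels = {c.representative_id: truth.family_of(c.representative_id)
                  for c in small_clusters}
        cand = [10.0 ** (-k) for k in range(13, 86, 6)]
        scan = scan_thresholds(small_rep_net, labels, cand)
        tied = scan.table.loc[
            scan.table["combined"] == scan.table["combined"].max(), "cutoff"]
        assert scan.selected_cutoff == tied.min()

    def test_no_labeled_nodes_rejected(self, small_rep_net):
        with pytest.raises(InputError):
            scan_thresholds(small_rep_net, {}, [1e-20])

    def test_majority_labels_from_partial_annotation(self, small_clusters,
                                                     small_superfamily):
        # Node class labels built through the majority rule over the
        # annotated minority agree with the planted family classes.
        _, truth = small_superfamily
        for cl in small_clusters:
            got = majority_label(truth.class_labels[m] for m in cl.member_ids)
            if got is not None:
                fam = truth.family_of(cl.representative_id)
                assert got == truth.family_class[fam]
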