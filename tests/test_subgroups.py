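"""Thresholding, components, and the subgroup designation rules."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssnkit.networks import RepCluster, SimilarityNetwork, build_rep_network
from ssnkit.records import InputError
from ssnkit.subgroups import (
    apply_threshold,
    connected_components,
    designate_subgroups,
    propagate_members,
)

from conftest import components_by_transitive_closure


def _evalue_net(n_nodes, edges, clusters=None):
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n_nodes))
    for u, v, e in edges:
        g.add_edge(f"n{u}", f"n{v}", e_value=e, percent_identity=50.0,
                   alignment_length=100)
    return SimilarityNetwork(graph=g, node_kind="representative",
                             clusters=clusters or {})


class TestApplyThreshold:
    def test_keeps_edges_at_or_below_cutoff(self):
        net = _evalue_net(4, [(0, 1, 1e-10), (1, 2, 1e-14), (2, 3, 1e-30)])
        thr = apply_threshold(net, 1e-13)
        kept = {frozenset(e) for e in thr.graph.edges}
        assert kept == {frozenset(("n1", "n2")), frozenset(("n2", "n3"))}
        assert net.graph.number_of_edges() == 3  # original untouched

    def test_infinite_cutoff_keeps_all(self):
        net = _evalue_net(3, [(0, 1, 5.0), (1, 2, 1e-40)])
        assert apply_threshold(net, float("inf")).graph.number_of_edges() == 2

    @given(st.lists(st.tuples(st.integers(0, 14), st.integers(0, 14),
                              st.floats(1e-60, 10.0)), max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_monotone_nesting_over_cutoff_grid(self, raw_edges):
        edges = [(u, v, e) for u, v, e in raw_edges if u != v]
        net = _evalue_net(15, edges)
        grid = [10.0 ** (-k) for k in range(5, 41, 5)]
        previous_edges = None
        previous_comps = None
        for cutoff in grid:  # decreasing cutoff = increasing stringency
            thr = apply_threshold(net, cutoff)
            edge_set = {frozenset(e) for e in thr.graph.edges}
            comps = connected_components(thr)
            if previous_edges is not None:
                assert edge_set <= previous_edges
                # components refine: each new component inside one old one
                old_of = {n: i for i, c in enumerate(previous_comps) for n in c}
                for comp in comps:
                    assert len({old_of[n] for n in comp}) == 1
            previous_edges, previous_comps = edge_set, comps


class TestConnectedComponents:
    def test_two_triangles(self):
        net = _evalue_net(6, [(0, 1, 1e-20), (1, 2, 1e-20), (0, 2, 1e-20),
                              (3, 4, 1e-20), (4, 5, 1e-20), (3, 5, 1e-20)])
        comps = connected_components(net)
        assert sorted(len(c) for c in comps) == [3, 3]

    def test_no_edges_all_singletons(self):
        assert len(connected_components(_evalue_net(5, []))) == 5

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 61))
            m = int(rng.integers(0, 2 * n))
            edges = [(int(rng.integers(n)), int(rng.integers(n)), 1e-20)
                     for _ in range(m)]
            edges = [(u, v, e) for u, v, e in edges if u != v]
            net = _evalue_net(n, edges)
            got = connected_components(net)
            want = components_by_transitive_closure(
                net.graph.nodes, [(f"n{u}", f"n{v}") for u, v, _ in edges])
            assert got == want


def _cluster_net(sizes, edges):
    """Network of representative nodes r0.. with given member counts."""
    clusters = {
        f"r{i}": RepCluster(f"r{i}", tuple([f"r{i}"] + [f"r{i}m{j}" for j in range(s - 1)]), 0.5)
        for i, s in enumerate(sizes)
    }
    g = nx.Graph()
    g.add_nodes_from(clusters)
    for u, v, e in edges:
        g.add_edge(f"r{u}", f"r{v}", e_value=e, percent_identity=50.0,
                   alignment_length=100)
    return SimilarityNetwork(graph=g, node_kind="representative", clusters=clusters)


class TestDesignateSubgroups:
    def test_49_members_not_a_subgroup_50_is(self):
        # The size rule counts member sequences, with an inclusive >= bound.
        for total, expect in ((49, 0), (50, 1)):
            net = _cluster_net([total - 10, 10], [(0, 1, 1e-20)])
            res = designate_subgroups(net, 1e-13, min_members=50)
            assert len(res.subgroups) == expect

    def test_member_count_rule_counts_sequences_not_nodes(self):
        # Three representative nodes totaling 59 member sequences qualify.
        net = _cluster_net([20, 20, 19], [(0, 1, 1e-20), (1, 2, 1e-20)])
        res = designate_subgroups(net, 1e-13, min_members=50)
        assert len(res.subgroups) == 1
        assert res.subgroups[0].member_count == 59
        assert len(res.subgroups[0].node_ids) == 3

    def test_auto_names_by_descending_member_count(self):
        net = _cluster_net([10, 30, 25], [])
        res = designate_subgroups(net, 1e-13, min_members=5)
        names = {sg.name: sg.member_count for sg in res.subgroups}
        assert names == {"G1": 30, "G2": 25, "G3": 10}

    def test_label_map_overrides_auto_names(self):
        net = _cluster_net([30, 25], [])
        res = designate_subgroups(net, 1e-13, min_members=5,
                                  label_map={"r0": "Main"})
        assert {sg.name for sg in res.subgroups} == {"Main", "G2"}

    def test_level2_named_under_parent(self):
        net = _cluster_net([20, 20, 20, 20],
                           [(0, 1, 1e-20), (2, 3, 1e-20), (1, 2, 1e-15)])
        level1 = designate_subgroups(net, 1e-13, min_members=10)
        assert len(level1.subgroups) == 1
        level2 = designate_subgroups(net, 1e-18, min_members=10, level=2,
                                     parent_assignment=level1)
        assert {sg.name for sg in level2.subgroups} == {"G1.1", "G1.2"}
        assert all(sg.parent == "G1" for sg in level2.subgroups)

    def test_level2_requires_parent_assignment(self):
        net = _cluster_net([60], [])
        with pytest.raises(InputError):
            designate_subgroups(net, 1e-25, level=2)

    def test_small_components_recorded_unassigned(self):
        net = _cluster_net([60, 3], [])
        res = designate_subgroups(net, 1e-13, min_members=50)
        assert len(res.subgroups) == 1
        assert len(res.unassigned) == 1
        assert res.unassigned[0].is_singleton

    def test_planted_groups_recovered(self, small_superfamily, small_rep_net,
                                      small_clusters):
        _records, truth = small_superfamily
        res = designate_subgroups(small_rep_net, 1e-13, min_members=5)
        got = sorted(sorted(sg.member_sequence_ids) for sg in res.subgroups)
        want = {}
        for sid, (grp, _f) in truth.assignments.items():
            want.setdefault(grp, []).append(sid)
        assert got == sorted(sorted(v) for v in want.values())


class TestPropagateMembers:
    def test_members_inherit_representative_subgroup(self):
        clusters = [RepCluster("R", ("R", "m1", "m2"), 0.5)]
        g = nx.Graph()
        g.add_node("R")
        net = SimilarityNetwork(graph=g, node_kind="representative",
                                clusters={"R": clusters[0]})
        res = designate_subgroups(net, 1e-13, min_members=1)
        labels = propagate_members(res, clusters)
        assert labels == {"R": "G1", "m1": "G1", "m2": "G1"}

    def test_unassigned_representative_propagates_none(self):
        clusters = [RepCluster("R", ("R", "m1"), 0.5)]
        net = SimilarityNetwork(graph=nx.Graph(), node_kind="representative",
                                clusters={"R": clusters[0]})
        net.graph.add_node("R")
        res = designate_subgroups(net, 1e-13, min_members=50)
        labels = propagate_members(res, clusters)
        assert labels == {"R": None, "m1": None}

    def test_conservation_of_member_counts(self, small_rep_net, small_clusters):
        res = designate_subgroups(small_rep_net, 1e-13, min_members=5)
        labels = propagate_members(res, small_clusters)
        assigned = sum(1 for v in labels.values() if v is not None)
        assert assigned == sum(sg.member_count for sg in res.subgroups)

    def test_missing_cluster_rejected(self):
        net = _cluster_net([5], [])
        res = designate_subgroups(net, 1e-13, min_members=1)
        with pytest.raises(InputError):
            propagate_members(res, [])
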