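"""Shared fixtures: small seeded synthetic superfamilies and their alignments."""

from __future__ import annotations

import numpy as np
import pytest

from ssnkit.align import ScoringScheme, all_by_all
from ssnkit.networks import (
    build_rep_network,
    greedy_identity_cluster,
    identity_lookup_from_pairs,
)
from ssnkit.simulate import SimulationConfig, generate_superfamily


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # 2 groups x 2 families x 6 members at single-domain lengths (~230
    # residues): long enough that cross-family pairs within a group clear the
    # level 1 cutoff, small enough for fast all-by-all alignment.
    return SimulationConfig(
        n_level1_groups=2,
        families_per_group=2,
        members_per_family=6,
        seq_length_profile=((225, 240, 1.0),),
        within_family_sub_rate=0.10,
        within_group_sub_rate=0.35,
        annotation_coverage=0.5,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_superfamily(small_config):
    return generate_superfamily(small_config)


@pytest.fixture(scope="session")
def small_pairs(small_superfamily):
    records, _truth = small_superfamily
    return all_by_all(records, ScoringScheme())


@pytest.fixture(scope="session")
def small_clusters(small_superfamily, small_pairs):
    records, _truth = small_superfamily
    return greedy_identity_cluster(
        records, 0.5, identity_lookup_from_pairs(small_pairs, records)
    )


@pytest.fixture(scope="session")
def small_rep_net(small_clusters, small_pairs):
    return build_rep_network(small_clusters, small_pairs)


def components_by_transitive_closure(nodes, edges):
    """Independent connected-components oracle: boolean reachability closure."""
    nodes = sorted(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in edges:
        reach[index[u], index[v]] = True
        reach[index[v], index[u]] = True
    for k in range(n):  # Floyd-Warshall style closure
        reach |= reach[:, k:k + 1] & reach[k:k + 1, :]
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        block = tuple(nodes[j] for j in range(n) if reach[i, j])
        seen.update(index[b] for b in block)
        comps.append(tuple(sorted(block)))
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def gapless_local_score(a: str, b: str, matrix) -> int:
    """Exhaustive enumeration of all gapless local alignments (oracle).

    Considers every pair of equal-length substrings of a and b and returns
    the maximum substitution-matrix sum (0 if nothing positive exists).
    """
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            score = 0
            for k in range(min(len(a) - i, len(b) - j)):
                score += matrix[a[i + k], b[j + k]]
                if score > best:
                    best = score
    return int(best)
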