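"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from anisoslice import VoxelSpec


def _is_linear_forest(G: nx.Graph, edges) -> bool:
    """True when an edge subset forms vertex-disjoint simple paths."""
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    H.add_edges_from(edges)
    if any(d > 2 for _, d in H.degree):
        return False
    try:
        nx.find_cycle(H)
        return False
    except nx.NetworkXNoCycle:
        return True


def min_path_cover_exhaustive(G: nx.Graph) -> int:
    """Exhaustive minimum node-disjoint path decomposition of a small graph.

    A decomposition into k paths uses exactly n - k edges forming a
    vertex-disjoint union of simple paths (a linear forest), so the minimum
    path count is n minus the largest linear forest.  Brute-forces edge
    subsets from largest to smallest; intended for graphs of <= ~12 nodes.
    """
    n = G.number_of_nodes()
    edges = list(G.edges)
    for k in range(min(len(edges), n - 1), 0, -1):
        for subset in combinations(edges, k):
            if _is_linear_forest(G, subset):
                return n - k
    return n


@pytest.fixture(scope="session")
def exhaustive_min_paths():
    return min_path_cover_exhaustive


@pytest.fixture(scope="session")
def symmetric_spec():
    """Fully symmetric single-material voxel: gamma must be exactly 1."""
    return VoxelSpec(w1=0.84, w2=0.84, h1=0.42, h2=0.42, L1=1.14, L2=1.14,
                     E1=100.0, E2=100.0)


@pytest.fixture(scope="session")
def reference_spec():
    """The 18-GA single-material reference voxel with 2:1 print heights."""
    return VoxelSpec(w1=0.84, w2=0.84, h1=0.84, h2=0.42, L1=1.14, L2=1.14,
                     E1=100.0, E2=100.0)


def random_specs(n: int, seed: int = 0) -> list[VoxelSpec]:
    """Random valid voxel specs spanning realistic printing ranges."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        d = rng.uniform(0.2, 1.5)
        w1 = w2 = d
        h1, h2 = rng.uniform(0.2 * d, 1.5 * d, size=2)
        s1, s2 = rng.uniform(0.0, d, size=2)
        E1, E2 = rng.uniform(5.0, 600.0, size=2)
        out.append(VoxelSpec(w1=w1, w2=w2, h1=h1, h2=h2,
                             L1=d + s2, L2=d + s1, E1=E1, E2=E2))
    return out


@pytest.fixture(scope="session")
def spec_sampler():
    return random_specs
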