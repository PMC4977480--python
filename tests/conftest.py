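"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's code paths: reachability is a
hand-written breadth-first search over plain adjacency dicts, so criticality,
SCC and deletion-minimality checks are independent of networkx-based
implementations.
"""

from __future__ import annotations

import itertools
import random
from collections import deque

import pytest

from signalnet import (
    ConstraintVector,
    GeneNetwork,
    derive_constraints,
    generate_target,
    mask_unknown,
    shuffle_edges,
)


# ---------------------------------------------------------------------------
# hand-written BFS oracles
# ---------------------------------------------------------------------------


def bfs_reachable(edges, start, banned=frozenset()):
    """Nodes reachable from start over edges, never entering banned nodes."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    if start in banned:
        return set()
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for succ in adj.get(node, ()):
            if succ not in seen and succ not in banned:
                seen.add(succ)
                queue.append(succ)
    return seen


def oracle_is_critical(network: GeneNetwork, gene: str) -> bool:
    """Node-removal reachability oracle for criticality."""
    if gene in (network.receptor, network.reporter):
        return True
    reach = bfs_reachable(network.edges, network.receptor, banned={gene})
    return network.reporter not in reach


def oracle_critical_set(network: GeneNetwork) -> set[str]:
    return {g for g in network.genes if oracle_is_critical(network, g)}


def oracle_shortest_paths(edges, start):
    """BFS distances from start; missing key means unreachable."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for succ in adj.get(node, ()):
            if succ not in dist:
                dist[succ] = dist[node] + 1
                queue.append(succ)
    return dist


# ---------------------------------------------------------------------------
# random instance factories
# ---------------------------------------------------------------------------


def random_digraph(seed, n_nodes=8, n_edges=16) -> GeneNetwork:
    """A random simple digraph with terminals guaranteed path-connected."""
    rng = random.Random(seed)
    genes = [f"g{i}" for i in range(n_nodes)]
    while True:
        pairs = [(u, v) for u in genes for v in genes if u != v]
        edges = rng.sample(pairs, min(n_edges, len(pairs)))
        candidates = [
            (s, t)
            for s in genes
            for t in genes
            if s != t and t in bfs_reachable(edges, s)
        ]
        if candidates:
            s, t = rng.choice(candidates)
            return GeneNetwork(genes, edges, s, t)


def synthetic_instance(seed, size_range=(8, 12), n_range=(3, 6), rate=0.20):
    """One benchmark instance: (target, masked constraints, reference)."""
    rng = random.Random(seed)
    size = rng.randint(*size_range)
    target = generate_target(size, 3, rng.randrange(2**31))
    constraints = derive_constraints(target)
    n = rng.randint(*n_range)
    masked = mask_unknown(target, constraints, n, rng.randrange(2**31))
    reference = shuffle_edges(target, rate, rng.randrange(2**31))
    return target, masked, reference


# ---------------------------------------------------------------------------
# deletion-minimality oracle
# ---------------------------------------------------------------------------


def oracle_min_deletions(network: GeneNetwork, ordering) -> int:
    """Smallest edge-deletion count killing every ordering violation.

    A violation is a path with all-noncritical interior between two
    nonconsecutive critical genes in the forward direction.  Enumerates
    deletion subsets in increasing cardinality; exact but exponential, so
    keep instances small.
    """
    seq = ordering.sequence
    noncrit = set(network.genes) - set(seq)

    def violated(edges) -> bool:
        for i in range(len(seq) - 2):
            reach = bfs_reachable(
                edges, seq[i], banned=set(seq) - {seq[i]} - set(seq[i + 2 :])
            )
            if any(seq[j] in reach for j in range(i + 2, len(seq))):
                return True
        return False

    edges = sorted(network.edges)
    if not violated(edges):
        return 0
    for k in range(1, len(edges) + 1):
        for subset in itertools.combinations(range(len(edges)), k):
            keep = [e for idx, e in enumerate(edges) if idx not in subset]
            if not violated(keep):
                return k
    raise AssertionError("unreachable: deleting all edges removes all paths")


# ---------------------------------------------------------------------------
# small named fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def chain() -> GeneNetwork:
    """s -> a -> b -> t."""
    return GeneNetwork("sabt", [("s", "a"), ("a", "b"), ("b", "t")], "s", "t")


@pytest.fixture
def parallel() -> GeneNetwork:
    """s -> a -> t and s -> b -> t."""
    return GeneNetwork(
        "sabt", [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")], "s", "t"
    )


def complete_constraints(network: GeneNetwork, criticals) -> ConstraintVector:
    crit = set(criticals) | {network.receptor, network.reporter}
    return ConstraintVector({g: 1 if g in crit else 0 for g in network.genes})
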