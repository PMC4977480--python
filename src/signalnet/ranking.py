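"""Critical-gene orderings: the Sloan baseline and the TopSoG ranking.

The constructor needs the critical genes arranged in the order the signal
traverses them from receptor to reporter.  Two strategies are provided:

* **Sloan** — a profile-reduction-style greedy ordering.  Each gene gets a
  static priority from its total degree and its (undirected) distance to
  the reporter; starting from the receptor, the algorithm repeatedly
  numbers the highest-priority gene on the current front (the unnumbered
  neighbours of the numbered set).  High degree and large distance to the
  reporter both raise priority, so well-connected hubs far from the
  reporter are ranked early.  The full ordering is then restricted to the
  critical genes.  Degree-driven ranking ignores signal-flow causality,
  which is exactly the weakness TopSoG addresses.

* **TopSoG** (topological sorting for general graphs) — respects causality
  even in cyclic networks.  Strongly connected components are contracted
  to super nodes (Kosaraju), each multi-gene component gets a designated
  *entrance* (the entry point minimizing summed within-component distances
  to the other entry points), and the resulting DAG is traversed by a
  guided depth-first search from the receptor's node.  When several
  unvisited successors compete, the one with the largest ``1/d_s - 1/d_t``
  score is taken — close to the receptor, far from the reporter — with
  both distances measured in the *original* network.  Super nodes are then
  expanded in place by the same guided DFS inside the component, started
  at its entrance.  The first-visit order restricted to the critical genes
  is the ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping

import networkx as nx

from .model import ConstructionError, GeneNetwork, InputError

logger = logging.getLogger(__name__)

SLOAN_W1 = 1.0  # weight of the degree term in Sloan priority
SLOAN_W2 = 2.0  # weight of the distance-to-reporter term


@dataclass(frozen=True)
class CriticalOrdering:
    """Linear order of critical genes from receptor to reporter."""

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise InputError("an ordering needs at least receptor and reporter")
        if len(set(self.sequence)) != len(self.sequence):
            raise InputError("ordering contains a repeated gene")

    @property
    def receptor(self) -> str:
        return self.sequence[0]

    @property
    def reporter(self) -> str:
        return self.sequence[-1]

    def __iter__(self):
        return iter(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SCCDecomposition:
    """Strongly connected components with optional per-component entrances."""

    components: tuple[frozenset[str], ...]
    entrances: dict[frozenset[str], str] = field(default_factory=dict)

    def component_of(self, gene: str) -> frozenset[str]:
        for comp in self.components:
            if gene in comp:
                return comp
        raise InputError(f"gene {gene!r} is in no component")


@dataclass(frozen=True)
class PriorityScore:
    """Guided-DFS score of a gene: ``1/d_s - 1/d_t``.

    ``d_s`` is the shortest directed path length from the receptor to the
    gene and ``d_t`` the shortest directed path length from the gene to the
    reporter, both in the original reference network; ``math.inf`` encodes
    unreachability with the convention ``1/inf = 0``, and ``1/0 = inf`` so
    the receptor itself scores ``+inf`` and the reporter ``-inf``.
    """

    d_s: float
    d_t: float

    @property
    def score(self) -> float:
        return _inv(self.d_s) - _inv(self.d_t)


def _inv(d: float) -> float:
    if d == 0:
        return math.inf
    if math.isinf(d):
        return 0.0
    return 1.0 / d


def priority_scores(network: GeneNetwork) -> dict[str, PriorityScore]:
    """Per-gene ``PriorityScore`` against the network's own terminals."""
    graph = network.to_networkx()
    from_s = nx.single_source_shortest_path_length(graph, network.receptor)
    to_t = nx.single_source_shortest_path_length(
        graph.reverse(copy=False), network.reporter
    )
    return {
        g: PriorityScore(from_s.get(g, math.inf), to_t.get(g, math.inf))
        for g in network.genes
    }


def _check_criticals(network: GeneNetwork, criticals: Iterable[str]) -> frozenset[str]:
    crit = frozenset(criticals)
    unknown = [g for g in crit if g not in network]
    if unknown:
        raise InputError(f"critical gene(s) not in network: {sorted(unknown)!r}")
    if network.receptor not in crit or network.reporter not in crit:
        raise InputError("receptor and reporter must be among the critical genes")
    return crit


def _restrict(
    full_order: Iterable[str], criticals: frozenset[str], network: GeneNetwork
) -> CriticalOrdering:
    """Restrict a total gene ranking to the criticals, terminals pinned."""
    receptor, reporter = network.receptor, network.reporter
    interior = [
        g for g in full_order if g in criticals and g not in (receptor, reporter)
    ]
    ranked = set(interior) | {receptor, reporter}
    leftovers = [g for g in network.genes if g in criticals and g not in ranked]
    if leftovers:
        logger.warning(
            "ranking did not reach %d critical gene(s); appended in gene order",
            len(leftovers),
        )
    return CriticalOrdering((receptor, *interior, *leftovers, reporter))


# ---------------------------------------------------------------------------
# Sloan baseline
# ---------------------------------------------------------------------------


def sloan_order(network: GeneNetwork, criticals: Iterable[str]) -> CriticalOrdering:
    """Sloan-style greedy ordering restricted to the critical genes.

    Priority of gene v is ``W1 * deg(v) + W2 * dist(v, reporter)`` with the
    distance taken on the undirected view (unreachable genes are treated as
    maximally distant).  Numbering starts at the receptor; at each step the
    maximum-priority gene adjacent to the numbered set is taken, ties broken
    by stable gene order.  If the front empties while genes remain, the best
    unnumbered gene overall is taken (disconnected inputs stay totally
    ordered).
    """
    crit = _check_criticals(network, criticals)
    graph = network.to_networkx()
    undirected = graph.to_undirected(as_view=True)
    degree = {g: graph.in_degree(g) + graph.out_degree(g) for g in network.genes}
    dist_t = dict(nx.single_source_shortest_path_length(undirected, network.reporter))
    far = len(network.genes)  # beyond any finite undirected distance
    rank = network.rank

    def priority(gene: str) -> float:
        return SLOAN_W1 * degree[gene] + SLOAN_W2 * dist_t.get(gene, far)

    numbered: list[str] = [network.receptor]
    placed = {network.receptor}
    front: set[str] = {
        v for v in undirected.neighbors(network.receptor) if v not in placed
    }
    while len(placed) < len(network.genes):
        pool = front if front else {g for g in network.genes if g not in placed}
        best = max(pool, key=lambda g: (priority(g), -rank[g]))
        numbered.append(best)
        placed.add(best)
        front.discard(best)
        front.update(v for v in undirected.neighbors(best) if v not in placed)
    return _restrict(numbered, crit, network)


# ---------------------------------------------------------------------------
# SCC machinery
# ---------------------------------------------------------------------------


def find_sccs(network: GeneNetwork) -> SCCDecomposition:
    """Strongly connected components (Kosaraju), entrances unset.

    Components are returned in stable order (by the smallest gene rank of
    their members).
    """
    graph = network.to_networkx()
    rank = network.rank
    comps = [
        frozenset(c) for c in nx.kosaraju_strongly_connected_components(graph)
    ]
    comps.sort(key=lambda c: min(rank[g] for g in c))
    return SCCDecomposition(components=tuple(comps))


def select_entrance(network: GeneNetwork, component: Iterable[str]) -> str:
    """Designated entrance of one strongly connected component.

    Entry points are component members with an incoming edge from outside;
    the entrance is the entry point whose sum of shortest-path distances
    (within the component's induced subnetwork) to the other entry points is
    minimal, ties broken by gene order.  Components with no entry point use
    the receptor when it is a member, otherwise the member with the best
    guided-DFS score.  Singleton components return their sole gene.
    """
    comp = frozenset(component)
    if not comp <= set(network.genes):
        raise InputError("component contains genes not in the network")
    if len(comp) == 1:
        return next(iter(comp))
    rank = network.rank
    entries = sorted(
        {v for (u, v) in network.edges if v in comp and u not in comp},
        key=lambda g: rank[g],
    )
    if not entries:
        if network.receptor in comp:
            return network.receptor
        scores = priority_scores(network)
        return max(comp, key=lambda g: (scores[g].score, -rank[g]))
    if len(entries) == 1:
        return entries[0]
    sub = network.to_networkx().subgraph(comp)
    best, best_key = None, None
    for entry in entries:
        lengths = nx.single_source_shortest_path_length(sub, entry)
        total = sum(lengths[other] for other in entries if other != entry)
        key = (total, rank[entry])
        if best_key is None or key < best_key:
            best, best_key = entry, key
    return best


def _condensed_digraph(
    network: GeneNetwork, decomposition: SCCDecomposition
) -> tuple[nx.DiGraph, dict[str, Hashable], dict[Hashable, frozenset[str]]]:
    """Condensed DAG over hashable node keys, plus the two membership maps.

    Singleton components keep their gene identifier as node key; multi-gene
    components get a ``("scc", i)`` key.
    """
    node_of: dict[str, Hashable] = {}
    members: dict[Hashable, frozenset[str]] = {}
    for i, comp in enumerate(decomposition.components):
        key: Hashable = next(iter(comp)) if len(comp) == 1 else ("scc", i)
        members[key] = comp
        for gene in comp:
            node_of[gene] = key
    condensed = nx.DiGraph()
    condensed.add_nodes_from(members)
    for u, v in network.edges:
        ku, kv = node_of[u], node_of[v]
        if ku != kv:
            condensed.add_edge(ku, kv)
    return condensed, node_of, members


def condense(network: GeneNetwork, decomposition: SCCDecomposition) -> GeneNetwork:
    """Replace each multi-gene component with a single super node.

    The result is acyclic by construction.  Super nodes are named
    ``__scc<i>__``.  Raises if receptor and reporter share one component,
    since the condensed network could not keep two distinct terminals.
    """
    condensed, node_of, members = _condensed_digraph(network, decomposition)
    if node_of[network.receptor] == node_of[network.reporter]:
        raise InputError(
            "receptor and reporter lie in the same strongly connected component"
        )

    def name(key: Hashable) -> str:
        return key if isinstance(key, str) else f"__scc{key[1]}__"

    rank = network.rank
    keys = sorted(members, key=lambda k: min(rank[g] for g in members[k]))
    result = GeneNetwork(
        [name(k) for k in keys],
        [(name(u), name(v)) for u, v in condensed.edges],
        name(node_of[network.receptor]),
        name(node_of[network.reporter]),
    )
    if not nx.is_directed_acyclic_graph(result.to_networkx()):  # pragma: no cover
        raise ConstructionError("condensed graph is not acyclic")
    return result


# ---------------------------------------------------------------------------
# Guided DFS and TopSoG
# ---------------------------------------------------------------------------


def _guided_dfs(
    graph: nx.DiGraph,
    start: Hashable,
    score_of: Callable[[Hashable], float],
    rank_of: Callable[[Hashable], int],
) -> list[Hashable]:
    """Depth-first first-visit order, best-scored unvisited successor next.

    Ties break by stable rank; nodes unreachable from the start are appended
    afterwards sorted by score descending then rank, so the order is total.
    """
    visited: set[Hashable] = set()
    order: list[Hashable] = []
    stack: list[Hashable] = [start]
    while stack:
        node = stack[-1]
        if node not in visited:
            visited.add(node)
            order.append(node)
        candidates = [v for v in graph.successors(node) if v not in visited]
        if candidates:
            stack.append(max(candidates, key=lambda v: (score_of(v), -rank_of(v))))
        else:
            stack.pop()
    rest = sorted(
        (n for n in graph.nodes if n not in visited),
        key=lambda v: (-score_of(v), rank_of(v)),
    )
    return order + rest


def guided_dfs_order(
    network: GeneNetwork,
    start: str,
    priority: Mapping[str, PriorityScore] | None = None,
) -> list[str]:
    """Guided DFS over a network's genes from ``start``.

    ``priority`` defaults to scores computed against the network itself;
    pass scores computed on the original reference network when traversing a
    derived (e.g. condensed or induced) graph.
    """
    if start not in network:
        raise InputError(f"start gene {start!r} not in network")
    scores = priority if priority is not None else priority_scores(network)
    rank = network.rank
    return _guided_dfs(
        network.to_networkx(),
        start,
        lambda g: scores[g].score,
        lambda g: rank[g],
    )


def topsog_order(network: GeneNetwork, criticals: Iterable[str]) -> CriticalOrdering:
    """TopSoG ranking of the critical genes.

    Pipeline: find SCCs, pick entrances, condense to a DAG, guided DFS from
    the receptor's node with scores from the original network (super nodes
    score as their entrance), expand super nodes in place by guided DFS
    inside the component from its entrance, then restrict to the criticals.
    """
    crit = _check_criticals(network, criticals)
    decomposition = find_sccs(network)
    for comp in decomposition.components:
        decomposition.entrances[comp] = select_entrance(network, comp)
    condensed, node_of, members = _condensed_digraph(network, decomposition)
    scores = priority_scores(network)
    rank = network.rank

    def key_score(key: Hashable) -> float:
        comp = members[key]
        gene = key if isinstance(key, str) else decomposition.entrances[comp]
        return scores[gene].score

    def key_rank(key: Hashable) -> int:
        return min(rank[g] for g in members[key])

    condensed_order = _guided_dfs(
        condensed, node_of[network.receptor], key_score, key_rank
    )
    graph = network.to_networkx()
    full: list[str] = []
    for key in condensed_order:
        comp = members[key]
        if len(comp) == 1:
            full.append(next(iter(comp)))
        else:
            # the whole traversal starts from the receptor, so its own
            # component expands from the receptor, not the entrance
            start = (
                network.receptor
                if network.receptor in comp
                else decomposition.entrances[comp]
            )
            sub = graph.subgraph(comp)
            full.extend(
                _guided_dfs(
                    sub,
                    start,
                    lambda g: scores[g].score,
                    lambda g: rank[g],
                )
            )
    return _restrict(full, crit, network)
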