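"""Consistent-network constructor: ordering-guided edge edits.

Given a reference network and a *complete* constraint vector (no unknown
entries), the constructor produces a network consistent with the
constraints at a small edge edit distance from the reference, in three
steps:

1. rank the constrained-critical genes from receptor to reporter (Sloan or
   TopSoG, see :mod:`signalnet.ranking`);
2. delete the reference edges that conflict with that ordering — any path
   whose interior genes are all noncritical connecting two *nonconsecutive*
   critical genes lets the signal bypass the critical genes in between, so
   for every consecutive pair ``(g_i, g_{i+1})`` a minimum edge cut (unit
   capacities, max-flow) separates ``g_i`` from all later critical genes in
   the subgraph whose interior is the noncritical genes with ``g_{i+1}``
   removed; the union of the per-pair cuts is deleted.  Backward edges
   (later segment to earlier segment) are left alone: they cannot create a
   receptor-to-reporter path that skips a critical gene;
3. insert the direct edge ``(g_i, g_{i+1})`` for every consecutive pair
   where either no interior-noncritical path exists (the chain would be
   broken) or some noncritical gene sits on *all* such paths (which would
   wrongly promote it to critical).

The result is guaranteed consistent with the constraints and is verified
before being returned.  Per-pair cuts make the deletion count near-minimal
rather than provably globally minimal; the gap is tracked statistically in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import networkx as nx

from .model import (
    CRITICAL,
    UNKNOWN,
    ConstraintVector,
    ConstructionError,
    GeneNetwork,
    InputError,
    critical_set,
    is_consistent,
    validate_constraints,
)
from .ranking import CriticalOrdering, sloan_order, topsog_order

RankingStrategy = Literal["sloan", "topsog"]

_RANKINGS = {"sloan": sloan_order, "topsog": topsog_order}


@dataclass(frozen=True)
class EditScript:
    """Edge edits turning the reference into the constructed network."""

    deleted: frozenset[tuple[str, str]]
    inserted: frozenset[tuple[str, str]]
    network: GeneNetwork

    @property
    def distance(self) -> int:
        return len(self.deleted) + len(self.inserted)

    def to_dict(self) -> dict:
        return {
            "deleted": sorted(map(list, self.deleted)),
            "inserted": sorted(map(list, self.inserted)),
            "distance": self.distance,
        }


@dataclass(frozen=True)
class SegmentAssignment:
    """Which consecutive-critical-pair segment each noncritical gene serves.

    ``segments[u]`` lists every index ``i`` such that ``u`` is reachable
    from ``g_i`` and can reach ``g_{i+1}`` through noncritical interiors;
    genes qualifying for no segment are ``off_path``.
    """

    segments: dict[str, tuple[int, ...]]
    off_path: frozenset[str]


def _noncritical_genes(network: GeneNetwork, ordering: CriticalOrdering) -> set[str]:
    return set(network.genes) - set(ordering.sequence)


def _reachable_via(
    graph: nx.DiGraph, start: str, allowed_interior: set[str]
) -> set[str]:
    """Genes reachable from ``start`` via paths with interior in the set."""
    seen = {start}
    frontier = [start]
    reached: set[str] = set()
    while frontier:
        node = frontier.pop()
        for succ in graph.successors(node):
            if succ in seen:
                continue
            seen.add(succ)
            reached.add(succ)
            if succ in allowed_interior:
                frontier.append(succ)
    return reached


def has_interior_noncritical_path(
    network: GeneNetwork,
    source: str,
    target: str,
    noncritical: set[str] | None = None,
    ordering: CriticalOrdering | None = None,
) -> bool:
    """True iff a ``source -> target`` path with all-noncritical interior exists."""
    if noncritical is None:
        if ordering is None:
            raise InputError("pass either the noncritical set or the ordering")
        noncritical = _noncritical_genes(network, ordering)
    return target in _reachable_via(network.to_networkx(), source, noncritical)


def assign_segments(
    network: GeneNetwork, ordering: CriticalOrdering
) -> SegmentAssignment:
    """Map noncritical genes to the critical-pair segments they can serve."""
    seq = ordering.sequence
    noncrit = _noncritical_genes(network, ordering)
    graph = network.to_networkx()
    reverse = graph.reverse(copy=False)
    forward = [_reachable_via(graph, seq[i], noncrit) for i in range(len(seq) - 1)]
    backward = [_reachable_via(reverse, seq[i + 1], noncrit) for i in range(len(seq) - 1)]
    segments: dict[str, tuple[int, ...]] = {}
    off_path: set[str] = set()
    for gene in network.genes:
        if gene not in noncrit:
            continue
        hits = tuple(
            i
            for i in range(len(seq) - 1)
            if gene in forward[i] and gene in backward[i]
        )
        if hits:
            segments[gene] = hits
        else:
            off_path.add(gene)
    return SegmentAssignment(segments=segments, off_path=frozenset(off_path))


def _min_cut_edges(
    network: GeneNetwork,
    allowed: set[str],
    source: str,
    sinks: list[str],
) -> set[tuple[str, str]]:
    """Minimum set of real edges separating source from the sinks.

    Operates on the subgraph induced by ``allowed``; real edges carry unit
    capacity and every sink is tied to a virtual super sink with infinite
    capacity, so cut edges are always real and never edges between sinks.
    """
    flow = nx.DiGraph()
    flow.add_nodes_from(allowed)
    for u, v in network.edges:
        if u in allowed and v in allowed:
            flow.add_edge(u, v, capacity=1)
    super_sink = ("__sink__",)
    for sink in sinks:
        flow.add_edge(sink, super_sink, capacity=math.inf)
    if not nx.has_path(flow, source, super_sink):
        return set()
    _, (src_side, _) = nx.minimum_cut(flow, source, super_sink)
    return {
        (u, v)
        for u, v in flow.edges
        if u in src_side and v not in src_side and v != super_sink
    }


def delete_conflicting_edges(
    network: GeneNetwork, ordering: CriticalOrdering
) -> EditScript:
    """Remove the cheapest edge set killing all ordering-violating bypasses.

    After deletion no path with all-noncritical interior connects two
    nonconsecutive critical genes in the forward direction (including
    bypasses straight to the reporter).
    """
    seq = ordering.sequence
    noncrit = _noncritical_genes(network, ordering)
    deleted: set[tuple[str, str]] = set()
    for i in range(len(seq) - 2):
        later = list(seq[i + 2 :])
        allowed = {seq[i]} | noncrit | set(later)
        deleted |= _min_cut_edges(network, allowed, seq[i], later)
    result = network.replace_edges(network.edges - deleted)
    return EditScript(
        deleted=frozenset(deleted), inserted=frozenset(), network=result
    )


def insert_required_edges(
    network: GeneNetwork,
    ordering: CriticalOrdering,
    constraints: ConstraintVector,
) -> EditScript:
    """Insert direct consecutive-pair edges where the chain needs them.

    Applied after the deletion step.  For each consecutive critical pair
    ``(a, b)`` lacking a direct edge, the edge ``(a, b)`` is inserted when
    no interior-noncritical ``a -> b`` path exists (case 1) or when some
    noncritical gene sits on all such paths (case 2).  The resulting
    network is verified consistent with the full constraint vector.
    """
    seq = ordering.sequence
    noncrit = _noncritical_genes(network, ordering)
    graph = network.to_networkx()
    reverse = graph.reverse(copy=False)
    inserted: set[tuple[str, str]] = set()
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if (a, b) in network.edges:
            continue
        forward = _reachable_via(graph, a, noncrit)
        if b not in forward:
            inserted.add((a, b))  # case 1: the chain is broken here
            continue
        backward = _reachable_via(reverse, b, noncrit)
        carriers = (forward & backward & noncrit) - {a, b}
        for gene in sorted(carriers, key=lambda g: network.rank[g]):
            # case 2: does removing this noncritical gene sever a -> b?
            if b not in _reachable_via(graph, a, noncrit - {gene}):
                inserted.add((a, b))
                break
    result = network.replace_edges(network.edges | inserted)
    if not is_consistent(result, constraints):
        criticals = critical_set(result)
        offending = [
            g
            for g, v in constraints.items()
            if (v == CRITICAL) != (g in criticals) and v != UNKNOWN
        ]
        raise ConstructionError(
            f"constructed network violates constraints for genes {offending!r}"
        )
    return EditScript(
        deleted=frozenset(), inserted=frozenset(inserted), network=result
    )


def construct(
    reference: GeneNetwork,
    constraints: ConstraintVector,
    ranking_strategy: RankingStrategy = "topsog",
) -> EditScript:
    """Build a constraint-consistent network near the reference.

    Requires a complete constraint vector (resolving unknowns is the
    optimizers' job) with receptor and reporter constrained critical.
    Deterministic for fixed inputs and strategy.
    """
    validate_constraints(reference, constraints)
    if not constraints.is_complete:
        raise InputError(
            "constraint vector contains unknown (-1) entries; resolve them first"
        )
    for terminal in (reference.receptor, reference.reporter):
        if constraints[terminal] != CRITICAL:
            raise InputError(
                f"terminal gene {terminal!r} must be constrained critical"
            )
    if ranking_strategy not in _RANKINGS:
        raise InputError(f"unknown ranking strategy {ranking_strategy!r}")
    criticals = constraints.criticals()
    ordering = _RANKINGS[ranking_strategy](reference, criticals)
    deletion = delete_conflicting_edges(reference, ordering)
    insertion = insert_required_edges(deletion.network, ordering, constraints)
    deleted = set(deletion.deleted)
    inserted: set[tuple[str, str]] = set()
    for edge in insertion.inserted:
        if edge in deleted:  # re-adding a cut edge: keep it instead
            deleted.discard(edge)
        else:
            inserted.add(edge)
    network = reference.replace_edges((reference.edges - deleted) | inserted)
    return EditScript(
        deleted=frozenset(deleted), inserted=frozenset(inserted), network=network
    )


def violating_pairs(
    network: GeneNetwork, ordering: CriticalOrdering
) -> list[tuple[str, str]]:
    """Nonconsecutive forward critical pairs joined by a noncritical bypass.

    Empty exactly when the network respects the ordering; used by the
    deletion step's tests and the enumeration oracle.
    """
    seq = ordering.sequence
    noncrit = _noncritical_genes(network, ordering)
    graph = network.to_networkx()
    pairs = []
    for i in range(len(seq) - 2):
        reached = _reachable_via(graph, seq[i], noncrit)
        for j in range(i + 2, len(seq)):
            if seq[j] in reached:
                pairs.append((seq[i], seq[j]))
    return pairs
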