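"""Core data model: directed gene networks, RNAi constraints, criticality.

A signaling pathway is modelled as a simple directed graph over named genes
with two designated terminals: the *receptor* (where an external signal
enters the cell) and the *reporter* (the read-out gene at the end of the
cascade).  A single-gene-knockdown RNAi experiment tells us, per gene,
whether knocking it down blocks signal flow from receptor to reporter.  A
gene that lies on *every* directed receptor-to-reporter path is called
*critical*: deleting it disconnects the two terminals.  Per-gene RNAi
outcomes are encoded as a constraint vector with entries in

* ``1``  -- critical (knockdown blocks the signal),
* ``0``  -- noncritical (signal still arrives),
* ``-1`` -- unknown (the experiment is missing).

A network is *consistent* with a constraint vector when every gene
constrained ``1`` is critical and every gene constrained ``0`` is not;
unknown entries impose nothing.  The distance between two networks on the
same gene set is the size of the symmetric difference of their directed
edge sets — the number of single-edge edits separating them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

CRITICAL = 1
NONCRITICAL = 0
UNKNOWN = -1

_VALID_CONSTRAINTS = frozenset({CRITICAL, NONCRITICAL, UNKNOWN})


class SignalNetError(Exception):
    """Base class for errors raised by this package."""


class InputError(SignalNetError, ValueError):
    """Invalid user-supplied input (bad gene, malformed file, bad domain)."""


class ConstructionError(SignalNetError, RuntimeError):
    """The constructor failed to produce a consistent network (guards bugs)."""


class GeneNetwork:
    """A simple directed network over named genes with designated terminals.

    Parameters
    ----------
    genes:
        Gene identifiers in a stable order.  The order is preserved and used
        for deterministic tie-breaking throughout the package (orderings,
        hill-climbing sweeps, entrance selection).
    edges:
        Directed gene pairs.  Self-loops are rejected; duplicate edges are
        collapsed with a logged warning.
    receptor, reporter:
        The two distinct terminal genes.
    """

    __slots__ = ("genes", "edges", "receptor", "reporter", "_graph", "_rank")

    def __init__(
        self,
        genes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        receptor: str,
        reporter: str,
    ) -> None:
        gene_tuple = tuple(dict.fromkeys(genes))
        gene_set = set(gene_tuple)
        if len(gene_tuple) < 2:
            raise InputError("a network needs at least two genes")
        if receptor not in gene_set:
            raise InputError(f"receptor {receptor!r} is not a gene of the network")
        if reporter not in gene_set:
            raise InputError(f"reporter {reporter!r} is not a gene of the network")
        if receptor == reporter:
            raise InputError("receptor and reporter must be distinct genes")

        seen: set[tuple[str, str]] = set()
        duplicates = 0
        for u, v in edges:
            if u not in gene_set:
                raise InputError(f"edge endpoint {u!r} is not a gene of the network")
            if v not in gene_set:
                raise InputError(f"edge endpoint {v!r} is not a gene of the network")
            if u == v:
                raise InputError(f"self-loop on gene {u!r} is not allowed")
            if (u, v) in seen:
                duplicates += 1
            else:
                seen.add((u, v))
        if duplicates:
            logger.warning("collapsed %d duplicate edge(s)", duplicates)

        object.__setattr__(self, "genes", gene_tuple)
        object.__setattr__(self, "edges", frozenset(seen))
        object.__setattr__(self, "receptor", receptor)
        object.__setattr__(self, "reporter", reporter)
        object.__setattr__(self, "_graph", None)
        object.__setattr__(self, "_rank", None)

    def __setattr__(self, name: str, value) -> None:  # pragma: no cover
        raise AttributeError("GeneNetwork is immutable")

    # -- containers ----------------------------------------------------

    def __contains__(self, gene: str) -> bool:
        return gene in self.rank

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.edges == other.edges
            and self.receptor == other.receptor
            and self.reporter == other.reporter
        )

    def __hash__(self) -> int:
        return hash((self.genes, self.edges, self.receptor, self.reporter))

    def __repr__(self) -> str:
        return (
            f"GeneNetwork({len(self.genes)} genes, {len(self.edges)} edges, "
            f"{self.receptor!r}->{self.reporter!r})"
        )

    # -- views ---------------------------------------------------------

    @property
    def rank(self) -> dict[str, int]:
        """Stable gene -> position map used for deterministic tie-breaks."""
        if self._rank is None:
            object.__setattr__(
                self, "_rank", {g: i for i, g in enumerate(self.genes)}
            )
        return self._rank

    def to_networkx(self) -> nx.DiGraph:
        """Directed-graph view (cached; treat as read-only)."""
        if self._graph is None:
            graph = nx.DiGraph()
            graph.add_nodes_from(self.genes)
            graph.add_edges_from(self.edges)
            object.__setattr__(self, "_graph", graph)
        return self._graph

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges sorted by stable gene order (deterministic output order)."""
        rank = self.rank
        return sorted(self.edges, key=lambda e: (rank[e[0]], rank[e[1]]))

    # -- derivation ----------------------------------------------------

    def replace_edges(self, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        """A network on the same genes/terminals with a different edge set."""
        return GeneNetwork(self.genes, edges, self.receptor, self.reporter)

    def with_terminals(self, receptor: str, reporter: str) -> "GeneNetwork":
        """The same network with a different receptor/reporter designation."""
        return GeneNetwork(self.genes, self.edges, receptor, reporter)


class ConstraintVector(Mapping):
    """Per-gene RNAi constraint map with values in ``{1, 0, -1}``.

    Behaves as an immutable mapping from gene identifier to constraint value.
    Iteration order follows insertion order of the backing mapping, which by
    convention matches the network's stable gene order.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, int]) -> None:
        checked: dict[str, int] = {}
        for gene, value in values.items():
            if value not in _VALID_CONSTRAINTS:
                raise InputError(
                    f"constraint for gene {gene!r} must be 1, 0 or -1, got {value!r}"
                )
            checked[gene] = int(value)
        self._values = checked

    def __getitem__(self, gene: str) -> int:
        return self._values[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        n_crit = sum(1 for v in self._values.values() if v == CRITICAL)
        n_unk = sum(1 for v in self._values.values() if v == UNKNOWN)
        return (
            f"ConstraintVector({len(self._values)} genes, "
            f"{n_crit} critical, {n_unk} unknown)"
        )

    def unknowns(self) -> tuple[str, ...]:
        """Genes whose RNAi constraint is missing, in stable order."""
        return tuple(g for g, v in self._values.items() if v == UNKNOWN)

    def criticals(self) -> frozenset[str]:
        return frozenset(g for g, v in self._values.items() if v == CRITICAL)

    @property
    def is_complete(self) -> bool:
        return all(v != UNKNOWN for v in self._values.values())

    def updated(self, changes: Mapping[str, int]) -> "ConstraintVector":
        merged = dict(self._values)
        merged.update(changes)
        return ConstraintVector(merged)


def validate_constraints(network: GeneNetwork, constraints: ConstraintVector) -> None:
    """Check the constraint domain matches the network's gene set.

    Also enforces that the receptor and reporter are never constrained
    noncritical: by definition they lie on every receptor-to-reporter path,
    so a 0 there is unsatisfiable.
    """
    missing = [g for g in network.genes if g not in constraints]
    extra = [g for g in constraints if g not in network]
    if missing or extra:
        raise InputError(
            "constraint domain does not match the gene set"
            f" (missing: {missing!r}, extra: {extra!r})"
        )
    for terminal in (network.receptor, network.reporter):
        if constraints[terminal] == NONCRITICAL:
            raise InputError(
                f"terminal gene {terminal!r} cannot be constrained noncritical"
            )


def critical_set(network: GeneNetwork) -> frozenset[str]:
    """All genes lying on every directed receptor-to-reporter path.

    Computed through the dominator tree rooted at the receptor: a gene sits
    on every receptor-to-reporter path exactly when it dominates the
    reporter.  When no receptor-to-reporter path exists at all, the defining
    universal quantification is vacuously true and *every* gene is reported
    critical; constructed networks always contain such a path, so this arises
    only on raw inputs.
    """
    graph = network.to_networkx()
    source, target = network.receptor, network.reporter
    if not nx.has_path(graph, source, target):
        return frozenset(network.genes)
    idom = nx.immediate_dominators(graph, source)
    result = {target}
    node = target
    while node != source:
        node = idom[node]
        result.add(node)
    return frozenset(result)


def is_critical(network: GeneNetwork, gene: str) -> bool:
    """True iff every receptor-to-reporter path contains ``gene``.

    Equivalent to: removing the gene (with its incident edges) leaves the
    reporter unreachable from the receptor.  The receptor and reporter are
    always critical.
    """
    if gene not in network:
        raise InputError(f"unknown gene {gene!r}")
    return gene in critical_set(network)


def is_consistent(network: GeneNetwork, constraints: ConstraintVector) -> bool:
    """True iff the network satisfies every non-unknown RNAi constraint."""
    validate_constraints(network, constraints)
    criticals = critical_set(network)
    for gene, value in constraints.items():
        if value == CRITICAL and gene not in criticals:
            return False
        if value == NONCRITICAL and gene in criticals:
            return False
    return True


def distance(network_a: GeneNetwork, network_b: GeneNetwork) -> int:
    """Edge edit distance: size of the symmetric difference of edge sets."""
    if set(network_a.genes) != set(network_b.genes):
        raise InputError("distance requires networks on the same gene set")
    return len(network_a.edges ^ network_b.edges)
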