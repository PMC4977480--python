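"""Resolving unknown RNAi constraints: hill climbing and exhaustive search.

With ``n`` genes lacking RNAi data, each may be critical or noncritical, so
the true optimum requires evaluating all ``2^n`` configurations.  Real
signaling networks have few critical genes, so both heuristics start from
the all-noncritical resolution and only ever flip unknowns from
noncritical to critical (never back):

* **holistic** — in every sweep, tentatively flip each still-noncritical
  unknown gene, construct the candidate network, and accept the single
  flip giving the smallest distance to the reference if it strictly
  improves on the current best; stop when no flip improves.  Up to
  ``O(n^2)`` constructions.

* **prioritized** — first probe each unknown alone (its single-flip
  distance ``Dist[i]``; smaller means more likely critical), partition the
  unknowns into groups of equal ``Dist``, then run the holistic climb
  restricted to one group at a time in increasing ``Dist`` order —
  ``O(sum n_i^2)`` constructions plus the ``n`` probes.

* **exhaustive** — enumerate every assignment (capped ``n``); exactly
  ``2^n`` constructions.  Ties prefer fewer critical genes, then the
  lexicographically smallest assignment.

Constructions are memoized per run on the resolved critical subset (the
constructor is deterministic), and ``constructor_calls`` counts actual
constructions.  Both heuristics skip climbing when the baseline distance
is already zero, which no flip can improve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

from .construct import EditScript, RankingStrategy, construct
from .model import (
    CRITICAL,
    NONCRITICAL,
    UNKNOWN,
    ConstraintVector,
    ConstructionError,
    GeneNetwork,
    InputError,
    distance,
    is_consistent,
    validate_constraints,
)

DEFAULT_EXHAUSTIVE_CAP = 20


@dataclass
class InferenceResult:
    """Outcome of resolving the unknown constraints of one instance.

    ``trace`` logs each accepted climbing step as ``(gene, distance)``;
    ``dist_table`` and ``groups`` are populated by the prioritized method
    only (the initial single-flip distances and the equal-distance gene
    groups in processing order).
    """

    network: GeneNetwork
    resolved_constraints: ConstraintVector
    distance_to_reference: int
    constructor_calls: int
    trace: tuple[tuple[str, int], ...] = ()
    dist_table: dict[str, int] | None = None
    groups: tuple[tuple[str, ...], ...] | None = None


class _Constructor:
    """Memoized, call-counting wrapper around :func:`construct`.

    Keyed on the subset of unknown genes resolved critical; cache hits do
    not count as constructor calls.
    """

    def __init__(
        self,
        reference: GeneNetwork,
        base: ConstraintVector,
        ranking_strategy: RankingStrategy,
        memoize: bool = True,
    ) -> None:
        self.reference = reference
        self.base = base
        self.ranking_strategy = ranking_strategy
        self.memoize = memoize
        self.calls = 0
        self._cache: dict[frozenset[str], EditScript] = {}

    def __call__(self, critical_unknowns: frozenset[str]) -> EditScript:
        if self.memoize and critical_unknowns in self._cache:
            return self._cache[critical_unknowns]
        resolved = self.base.updated({g: CRITICAL for g in critical_unknowns})
        script = construct(self.reference, resolved, self.ranking_strategy)
        self.calls += 1
        if self.memoize:
            self._cache[critical_unknowns] = script
        return script


def initialize_noncritical(constraints: ConstraintVector) -> ConstraintVector:
    """Resolve every unknown (-1) entry to noncritical (0)."""
    return constraints.updated(
        {g: NONCRITICAL for g, v in constraints.items() if v == UNKNOWN}
    )


def _finalize(
    reference: GeneNetwork,
    ctor: _Constructor,
    accepted: frozenset[str],
    trace: list[tuple[str, int]],
    dist_table: dict[str, int] | None = None,
    groups: tuple[tuple[str, ...], ...] | None = None,
) -> InferenceResult:
    script = ctor(accepted)
    resolved = ctor.base.updated({g: CRITICAL for g in accepted})
    if not is_consistent(script.network, resolved):  # pragma: no cover
        raise ConstructionError("inferred network is not consistent")
    return InferenceResult(
        network=script.network,
        resolved_constraints=resolved,
        distance_to_reference=distance(script.network, reference),
        constructor_calls=ctor.calls,
        trace=tuple(trace),
        dist_table=dist_table,
        groups=groups,
    )


def _prepare(
    reference: GeneNetwork,
    constraints: ConstraintVector,
    ranking_strategy: RankingStrategy,
    memoize: bool = True,
) -> tuple[tuple[str, ...], _Constructor]:
    validate_constraints(reference, constraints)
    unknowns = tuple(g for g in reference.genes if constraints[g] == UNKNOWN)
    base = initialize_noncritical(constraints)
    return unknowns, _Constructor(reference, base, ranking_strategy, memoize)


def _climb(
    ctor: _Constructor,
    candidates: Iterable[str],
    accepted: set[str],
    best: int,
    trace: list[tuple[str, int]],
    rank: dict[str, int],
) -> int:
    """Greedy best-single-flip climbing over ``candidates``; returns best."""
    pool = [g for g in candidates if g not in accepted]
    while pool and best > 0:
        probes = [(ctor(frozenset(accepted) | {g}).distance, rank[g], g) for g in pool]
        dist, _, gene = min(probes)
        if dist >= best:
            break
        best = dist
        accepted.add(gene)
        trace.append((gene, dist))
        pool.remove(gene)
    return best


def holistic(
    reference: GeneNetwork,
    constraints: ConstraintVector,
    ranking_strategy: RankingStrategy = "topsog",
) -> InferenceResult:
    """Hill climbing over the full unknown set, best single flip per sweep."""
    unknowns, ctor = _prepare(reference, constraints, ranking_strategy)
    accepted: set[str] = set()
    trace: list[tuple[str, int]] = []
    best = ctor(frozenset()).distance
    if best > 0:
        _climb(ctor, unknowns, accepted, best, trace, reference.rank)
    return _finalize(reference, ctor, frozenset(accepted), trace)


def prioritized(
    reference: GeneNetwork,
    constraints: ConstraintVector,
    ranking_strategy: RankingStrategy = "topsog",
) -> InferenceResult:
    """Hill climbing in groups of equal single-flip distance.

    Unknowns whose lone flip leaves the constructed network closer to the
    reference are the likeliest criticals, so their group climbs first.
    """
    unknowns, ctor = _prepare(reference, constraints, ranking_strategy)
    accepted: set[str] = set()
    trace: list[tuple[str, int]] = []
    rank = reference.rank
    best = ctor(frozenset()).distance
    if best == 0 or not unknowns:
        return _finalize(reference, ctor, frozenset(), trace, dist_table={}, groups=())
    dist_table = {g: ctor(frozenset({g})).distance for g in unknowns}
    grouped: dict[int, list[str]] = {}
    for gene in unknowns:
        grouped.setdefault(dist_table[gene], []).append(gene)
    groups = tuple(tuple(grouped[d]) for d in sorted(grouped))
    for group in groups:
        best = _climb(ctor, group, accepted, best, trace, rank)
    return _finalize(
        reference, ctor, frozenset(accepted), trace, dist_table=dist_table, groups=groups
    )


def exhaustive(
    reference: GeneNetwork,
    constraints: ConstraintVector,
    ranking_strategy: RankingStrategy = "topsog",
    max_n: int = DEFAULT_EXHAUSTIVE_CAP,
) -> InferenceResult:
    """Global optimum by enumerating all 2^n unknown-gene assignments."""
    unknowns, ctor = _prepare(reference, constraints, ranking_strategy, memoize=False)
    n = len(unknowns)
    if n > max_n:
        raise InputError(
            f"{n} unknown genes exceed the exhaustive cap of {max_n}; "
            "raise max_n explicitly to insist"
        )
    best: tuple[int, frozenset[str], EditScript] | None = None
    # sizes ascending then lexicographic: first strict minimum found wins,
    # realizing the fewer-criticals-then-lexicographic tie rule
    for size in range(n + 1):
        for combo in itertools.combinations(unknowns, size):
            assignment = frozenset(combo)
            script = ctor(assignment)
            if best is None or script.distance < best[0]:
                best = (script.distance, assignment, script)
    assert best is not None
    _, best_assign, winner = best
    resolved = ctor.base.updated({g: CRITICAL for g in best_assign})
    if not is_consistent(winner.network, resolved):  # pragma: no cover
        raise ConstructionError("inferred network is not consistent")
    return InferenceResult(
        network=winner.network,
        resolved_constraints=resolved,
        distance_to_reference=distance(winner.network, reference),
        constructor_calls=ctor.calls,
    )
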