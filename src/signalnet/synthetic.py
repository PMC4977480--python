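"""Synthetic benchmark generation: scale-free targets and noisy references.

The benchmark emulates the standard evaluation setting for reference-guided
signaling-network inference:

* *targets* are scale-free digraphs grown by Barabási–Albert preferential
  attachment (``density`` attachment edges per arriving node, so a target
  of ``size`` nodes has exactly ``density * (size - density)`` edges), each
  undirected attachment edge oriented by a seeded fair coin;
* the receptor/reporter pair spans a *diameter* of the target: among all
  finite shortest directed path lengths the maximum is found, and one
  extremal pair is picked reproducibly at random;
* *constraints* are derived from the target itself — the genes on all
  receptor-to-reporter paths are critical (1), the rest noncritical (0) —
  so every target is consistent with its own constraints by construction;
* ``n_unknown`` constraints are masked to unknown (-1), excluding the
  terminals whose criticality is definitional;
* *references* are degree-preserving edge shuffles of the target: a
  mutation rate ``r`` rewires ``r * |E|`` edges via ``ceil(r * |E| / 2)``
  double-edge swaps, each preserving every gene's in- and out-degree and
  rejected if it would create a self-loop or duplicate edge.

``make_benchmark`` materializes the full grid (default: sizes 50/75/100/125
x 10 replicates x rates 5%..35%, i.e. 40 targets and 280 references) as
plain-text artifacts plus a JSON manifest of per-item seeds, from which the
files regenerate byte-identically.
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx

from . import io
from .model import (
    CRITICAL,
    NONCRITICAL,
    UNKNOWN,
    ConstraintVector,
    GeneNetwork,
    InputError,
    SignalNetError,
    critical_set,
)

logger = logging.getLogger(__name__)

_SEED_BOUND = 2**31


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid of the synthetic study; defaults are the standard conditions."""

    sizes: tuple[int, ...] = (50, 75, 100, 125)
    density: int = 3
    replicates: int = 10
    mutation_rates: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    n_unknown: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(self.sizes))
        object.__setattr__(self, "mutation_rates", tuple(self.mutation_rates))
        if self.density < 1:
            raise InputError("density must be >= 1")
        if any(not 0 <= r < 1 for r in self.mutation_rates):
            raise InputError("mutation rates must satisfy 0 <= r < 1")
        if any(s <= self.density for s in self.sizes):
            raise InputError("every size must exceed the density")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.n_unknown >= min(self.sizes) - 2:
            raise InputError("n_unknown must be < size - 2 for every size")

    @classmethod
    def from_dict(cls, data: dict) -> "BenchmarkConfig":
        return cls(**data)


def generate_target(size: int, density: int, seed: int) -> GeneNetwork:
    """A scale-free directed target with diameter-spanning terminals.

    Deterministic per seed.  Node count is ``size``, edge count exactly
    ``density * (size - density)``.
    """
    if size <= density or density < 1:
        raise InputError("need size > density >= 1")
    rng = random.Random(seed)
    for _ in range(20):
        undirected = nx.barabasi_albert_graph(size, density, seed=rng.randrange(_SEED_BOUND))
        genes = tuple(f"g{i}" for i in range(size))
        edges = []
        for u, v in sorted(undirected.edges()):
            if rng.random() < 0.5:
                edges.append((f"g{u}", f"g{v}"))
            else:
                edges.append((f"g{v}", f"g{u}"))
        graph = nx.DiGraph()
        graph.add_nodes_from(genes)
        graph.add_edges_from(edges)
        pair = _diameter_pair(graph, genes, rng)
        if pair is not None:
            return GeneNetwork(genes, edges, *pair)
        logger.warning("no receptor-reporter pair found; regenerating")  # pragma: no cover
    raise SignalNetError("exhausted retries generating a connected target")  # pragma: no cover


def _diameter_pair(
    graph: nx.DiGraph, gene_order: tuple[str, ...], rng: random.Random
) -> tuple[str, str] | None:
    """A random pair realizing the largest finite shortest-path length."""
    rank = {g: i for i, g in enumerate(gene_order)}
    best_len = 0
    best_pairs: list[tuple[str, str]] = []
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, dist in lengths.items():
            if target == source:
                continue
            if dist > best_len:
                best_len = dist
                best_pairs = [(source, target)]
            elif dist == best_len:
                best_pairs.append((source, target))
    if not best_pairs:
        return None
    best_pairs.sort(key=lambda p: (rank[p[0]], rank[p[1]]))
    return best_pairs[rng.randrange(len(best_pairs))]


def select_receptor_reporter(network: GeneNetwork, seed: int) -> tuple[str, str]:
    """Pick terminals on a diameter of the network, reproducibly at random.

    Ignores any terminals the network already designates.
    """
    pair = _diameter_pair(network.to_networkx(), network.genes, random.Random(seed))
    if pair is None:
        raise InputError("network has no directed path of length >= 1")
    return pair


def derive_constraints(network: GeneNetwork) -> ConstraintVector:
    """Constraints the network itself satisfies: its critical genes are 1."""
    criticals = critical_set(network)
    return ConstraintVector(
        {g: CRITICAL if g in criticals else NONCRITICAL for g in network.genes}
    )


def mask_unknown(
    network: GeneNetwork, constraints: ConstraintVector, n: int, seed: int
) -> ConstraintVector:
    """Mask exactly ``n`` non-terminal constraints to unknown (-1)."""
    eligible = [
        g
        for g in network.genes
        if g not in (network.receptor, network.reporter)
    ]
    if n > len(eligible):
        raise InputError(
            f"cannot mask {n} genes; only {len(eligible)} non-terminal genes exist"
        )
    picked = random.Random(seed).sample(eligible, n)
    return constraints.updated({g: UNKNOWN for g in picked})


def shuffle_edges(network: GeneNetwork, rate: float, seed: int) -> GeneNetwork:
    """Degree-preserving perturbation rewiring ``rate * |E|`` edges.

    Performs ``ceil(rate * |E| / 2)`` successful directed double-edge swaps
    — replace ``(a,b), (c,d)`` with ``(a,d), (c,b)`` — rejecting swaps that
    would create a self-loop or a duplicate edge.  Every gene's in- and
    out-degree is preserved exactly.
    """
    if not 0 <= rate < 1:
        raise InputError("mutation rate must satisfy 0 <= rate < 1")
    edges = network.sorted_edges()
    swaps_needed = math.ceil(rate * len(edges) / 2)
    if swaps_needed == 0:
        return network.replace_edges(network.edges)
    rng = random.Random(seed)
    edge_set = set(edges)
    budget = max(1000, 200 * swaps_needed)
    done = 0
    attempts = 0
    while done < swaps_needed:
        attempts += 1
        if attempts > budget:
            raise SignalNetError(
                f"swap budget exhausted after {done}/{swaps_needed} swaps"
            )
        i = rng.randrange(len(edges))
        j = rng.randrange(len(edges))
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        if (a, d) in edge_set or (c, b) in edge_set:
            continue  # would create a duplicate edge
        edge_set.difference_update([(a, b), (c, d)])
        edge_set.update([(a, d), (c, b)])
        edges[i], edges[j] = (a, d), (c, b)
        done += 1
    return network.replace_edges(edge_set)


def motivating_fixture() -> tuple[GeneNetwork, frozenset[str]]:
    """The small network contrasting Sloan and TopSoG rankings.

    Genes ``v_a`` and ``v_b`` are constrained critical; ``v_a`` can pass
    the signal to ``v_b`` and both sit at distance 1 from the reporter, so
    causality demands ``v_a`` before ``v_b`` — yet ``v_b`` has the larger
    degree, which a degree-driven Sloan ranking rewards.  The four defining
    properties are asserted programmatically: (i) both genes lie on
    receptor-to-reporter paths, (ii) ``v_a`` reaches ``v_b``, (iii)
    ``deg(v_b) > deg(v_a)``, (iv) equal directed distance to the reporter.
    """
    genes = ("s", "v_a", "v_b", "x", "y1", "y2", "t")
    edges = [
        ("s", "v_a"),
        ("s", "x"),
        ("x", "v_a"),
        ("x", "v_b"),
        ("v_a", "v_b"),
        ("v_a", "t"),
        ("v_b", "t"),
        ("v_b", "y1"),
        ("v_b", "y2"),
    ]
    network = GeneNetwork(genes, edges, "s", "t")
    graph = network.to_networkx()
    for gene in ("v_a", "v_b"):
        assert nx.has_path(graph, "s", gene) and nx.has_path(graph, gene, "t"), (
            f"{gene} must lie on a receptor-to-reporter path"
        )
    assert nx.has_path(graph, "v_a", "v_b"), "v_a must reach v_b"
    deg = lambda g: graph.in_degree(g) + graph.out_degree(g)
    assert deg("v_b") > deg("v_a"), "v_b must have the larger degree"
    d_t = nx.single_source_shortest_path_length(graph.reverse(copy=False), "t")
    assert d_t["v_a"] == d_t["v_b"], "equal distance to the reporter required"
    return network, frozenset({"s", "v_a", "v_b", "t"})


def make_benchmark(config: BenchmarkConfig, out_dir: str | Path) -> dict:
    """Materialize the benchmark grid; returns (and writes) the manifest.

    Every artifact seed derives deterministically from ``config.seed``, so
    rerunning with the same config regenerates byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = random.Random(config.seed)
    targets = []
    for size in config.sizes:
        for rep in range(config.replicates):
            target_seed = master.randrange(_SEED_BOUND)
            mask_seed = master.randrange(_SEED_BOUND)
            shuffle_seeds = [
                master.randrange(_SEED_BOUND) for _ in config.mutation_rates
            ]
            target = generate_target(size, config.density, target_seed)
            constraints = derive_constraints(target)
            masked = mask_unknown(target, constraints, config.n_unknown, mask_seed)
            stem = f"target_s{size}_r{rep}"
            io.write_edge_tsv(target, out / f"{stem}.tsv")
            io.write_constraints(constraints, out / f"{stem}_constraints.tsv")
            io.write_constraints(masked, out / f"{stem}_masked.tsv")
            references = []
            for rate, sseed in zip(config.mutation_rates, shuffle_seeds):
                reference = shuffle_edges(target, rate, sseed)
                ref_path = f"reference_s{size}_r{rep}_m{round(rate * 100)}.tsv"
                io.write_edge_tsv(reference, out / ref_path)
                references.append({"rate": rate, "seed": sseed, "path": ref_path})
            targets.append(
                {
                    "size": size,
                    "replicate": rep,
                    "seed": target_seed,
                    "mask_seed": mask_seed,
                    "receptor": target.receptor,
                    "reporter": target.reporter,
                    "path": f"{stem}.tsv",
                    "constraints_path": f"{stem}_constraints.tsv",
                    "masked_path": f"{stem}_masked.tsv",
                    "references": references,
                }
            )
    manifest = {
        "config": asdict(config),
        "n_targets": len(targets),
        "n_references": sum(len(t["references"]) for t in targets),
        "targets": targets,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
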