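"""Readers and writers for the plain-text network and constraint formats.

Supported formats:

* edge-list TSV — one ``source<TAB>target`` line per edge; ``#``-prefixed
  comment lines are allowed.  Terminals may travel in header comments
  ``#receptor=<id>`` / ``#reporter=<id>``; an optional ``#genes=a,b,c``
  header pins the full stable gene order (and carries isolated genes).
* SIF dialect — ``source<TAB>activates<TAB>target``; the relation token is
  ignored on read and written as ``activates``.
* GraphML — directed graphs via networkx; terminals stored as graph
  attributes, constraints optionally round-tripped as the integer node
  attribute ``constraint``.
* constraint TSV — ``gene<TAB>value`` with value in {1, 0, -1}; genes of
  the network absent from the file default to -1 with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .model import UNKNOWN, ConstraintVector, GeneNetwork, InputError

logger = logging.getLogger(__name__)

_PathLike = str | Path


def _parse_edge_lines(
    lines: list[str], n_fields: int, path: _PathLike
) -> tuple[list[str], list[tuple[str, str]], dict[str, str]]:
    """Shared TSV/SIF parsing: returns (gene order, edges, header map)."""
    headers: dict[str, str] = {}
    order: dict[str, None] = {}
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                headers[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise InputError(
                f"{path}:{lineno}: expected {n_fields} tab-separated fields, "
                f"got {len(fields)}"
            )
        source, target = fields[0], fields[-1]
        order.setdefault(source)
        order.setdefault(target)
        edges.append((source, target))
    if "genes" in headers:
        order = dict.fromkeys(
            g.strip() for g in headers["genes"].split(",") if g.strip()
        ) | order
    return list(order), edges, headers


def _resolve_terminals(
    headers: dict[str, str],
    receptor: str | None,
    reporter: str | None,
    path: _PathLike,
) -> tuple[str, str]:
    receptor = receptor or headers.get("receptor")
    reporter = reporter or headers.get("reporter")
    if receptor is None or reporter is None:
        raise InputError(
            f"{path}: receptor/reporter not given and not found in headers"
        )
    return receptor, reporter


def read_edge_tsv(
    path: _PathLike, receptor: str | None = None, reporter: str | None = None
) -> GeneNetwork:
    """Read an edge-list TSV.  Explicit terminals override header comments."""
    lines = Path(path).read_text().splitlines()
    genes, edges, headers = _parse_edge_lines(lines, 2, path)
    receptor, reporter = _resolve_terminals(headers, receptor, reporter, path)
    return GeneNetwork(genes, edges, receptor, reporter)


def write_edge_tsv(network: GeneNetwork, path: _PathLike) -> None:
    out = [
        f"#receptor={network.receptor}",
        f"#reporter={network.reporter}",
        "#genes=" + ",".join(network.genes),
    ]
    out.extend(f"{u}\t{v}" for u, v in network.sorted_edges())
    Path(path).write_text("\n".join(out) + "\n")


def read_sif(
    path: _PathLike, receptor: str | None = None, reporter: str | None = None
) -> GeneNetwork:
    """Read a three-column SIF file (relation token ignored)."""
    lines = Path(path).read_text().splitlines()
    genes, edges, headers = _parse_edge_lines(lines, 3, path)
    receptor, reporter = _resolve_terminals(headers, receptor, reporter, path)
    return GeneNetwork(genes, edges, receptor, reporter)


def write_sif(network: GeneNetwork, path: _PathLike) -> None:
    out = [
        f"#receptor={network.receptor}",
        f"#reporter={network.reporter}",
        "#genes=" + ",".join(network.genes),
    ]
    out.extend(f"{u}\tactivates\t{v}" for u, v in network.sorted_edges())
    Path(path).write_text("\n".join(out) + "\n")


def read_graphml(
    path: _PathLike, receptor: str | None = None, reporter: str | None = None
) -> tuple[GeneNetwork, ConstraintVector | None]:
    """Read a directed GraphML file.

    Returns the network and, when every node carries an integer
    ``constraint`` attribute, the round-tripped constraint vector
    (otherwise ``None``).
    """
    graph = nx.read_graphml(path)
    if not graph.is_directed():
        raise InputError(f"{path}: GraphML graph must be directed")
    receptor = receptor or graph.graph.get("receptor")
    reporter = reporter or graph.graph.get("reporter")
    if receptor is None or reporter is None:
        raise InputError(
            f"{path}: receptor/reporter not given and not stored as graph attributes"
        )
    genes = [str(n) for n in graph.nodes]
    edges = [(str(u), str(v)) for u, v in graph.edges]
    network = GeneNetwork(genes, edges, str(receptor), str(reporter))
    constraints = None
    if all("constraint" in data for _, data in graph.nodes(data=True)):
        constraints = ConstraintVector(
            {str(n): int(data["constraint"]) for n, data in graph.nodes(data=True)}
        )
    return network, constraints


def write_graphml(
    network: GeneNetwork,
    path: _PathLike,
    constraints: ConstraintVector | None = None,
) -> None:
    graph = nx.DiGraph(receptor=network.receptor, reporter=network.reporter)
    graph.add_nodes_from(network.genes)
    graph.add_edges_from(network.sorted_edges())
    if constraints is not None:
        for gene in network.genes:
            graph.nodes[gene]["constraint"] = int(constraints[gene])
    nx.write_graphml(graph, path)


def read_constraints(path: _PathLike, network: GeneNetwork) -> ConstraintVector:
    """Read a ``gene<TAB>value`` constraint TSV for the given network.

    Genes of the network missing from the file default to -1 (unknown) with
    a logged warning; genes in the file but not in the network are an error.
    """
    values: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise InputError(
                f"{path}:{lineno}: expected 'gene<TAB>value', got {line!r}"
            )
        gene, text = fields
        if gene not in network:
            raise InputError(f"{path}:{lineno}: unknown gene {gene!r}")
        try:
            values[gene] = int(text)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: bad constraint value {text!r}") from exc
    missing = [g for g in network.genes if g not in values]
    if missing:
        logger.warning(
            "%s: %d gene(s) missing from constraint file default to unknown (-1)",
            path,
            len(missing),
        )
    return ConstraintVector(
        {g: values.get(g, UNKNOWN) for g in network.genes}
    )


def write_constraints(constraints: ConstraintVector, path: _PathLike) -> None:
    Path(path).write_text(
        "".join(f"{gene}\t{value}\n" for gene, value in constraints.items())
    )


def read_network(
    path: _PathLike, receptor: str | None = None, reporter: str | None = None
) -> GeneNetwork:
    """Dispatch on file extension: .sif, .graphml, else edge-list TSV."""
    suffix = Path(path).suffix.lower()
    if suffix == ".sif":
        return read_sif(path, receptor, reporter)
    if suffix == ".graphml":
        return read_graphml(path, receptor, reporter)[0]
    return read_edge_tsv(path, receptor, reporter)


def write_network(network: GeneNetwork, path: _PathLike) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".sif":
        write_sif(network, path)
    elif suffix == ".graphml":
        write_graphml(network, path)
    else:
        write_edge_tsv(network, path)
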