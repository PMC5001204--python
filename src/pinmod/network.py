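"""Undirected interaction-network I/O and utilities.

Networks are plain :class:`networkx.Graph` objects whose nodes are
upper-cased gene symbols. Edges may carry a ``sources`` attribute (a set of
database tags recording where the interaction was reported). All operations
treat edges as unordered pairs; self-loops are never admitted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "merge_networks",
    "induce_subnetwork",
    "extension_network",
    "find_hubs",
    "write_network",
]


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


def _norm(symbol: str, symbol_case: str) -> str:
    s = symbol.strip()
    return s.upper() if symbol_case == "upper" else s


def read_edge_list(
    path,
    dialect: str = "two_column",
    symbol_case: str = "upper",
    hprd_columns: tuple[int, int] = (0, 3),
) -> nx.Graph:
    """Read a tab/whitespace-separated edge list into an undirected graph.

    Parameters
    ----------
    dialect:
        ``two_column`` — interactors in the first two columns, an optional
        third column naming the source database.
        ``hprd_flat`` — flat-file layout where the interactor symbols sit in
        the columns given by ``hprd_columns`` (default 1 and 4).
    symbol_case:
        ``upper`` (default) upper-cases and strips symbols so that the two
        merged source databases agree on identifiers; ``preserve`` keeps them.

    Self-loops are dropped and duplicate undirected edges collapsed, with
    counts logged. An empty file yields a valid empty graph (warned).
    """
    if dialect not in ("two_column", "hprd_flat"):
        raise ValueError(f"unknown edge-list dialect: {dialect!r}")
    if symbol_case not in ("upper", "preserve"):
        raise ValueError(f"unknown symbol_case: {symbol_case!r}")
    ca, cb = (0, 1) if dialect == "two_column" else hprd_columns

    g = nx.Graph()
    n_loops = n_dups = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) <= max(ca, cb):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least {max(ca, cb) + 1} "
                    f"columns, got {len(fields)}"
                )
            a, b = _norm(fields[ca], symbol_case), _norm(fields[cb], symbol_case)
            if not a or not b:
                raise EdgeListParseError(f"{path}:{lineno}: empty gene symbol")
            source = None
            if dialect == "two_column" and len(fields) > 2 and fields[2].strip():
                source = fields[2].strip()
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                n_dups += 1
                if source:
                    g.edges[a, b].setdefault("sources", set()).add(source)
                continue
            attrs = {"sources": {source}} if source else {}
            g.add_edge(a, b, **attrs)
    if n_loops or n_dups:
        log.info(
            "read_edge_list(%s): dropped %d self-loops, collapsed %d duplicates",
            path, n_loops, n_dups,
        )
    if g.number_of_nodes() == 0:
        log.warning("read_edge_list(%s): empty network", path)
    return g


def merge_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Union of nodes and (unordered-deduplicated) edges of two networks.

    Source tags of edges present in both inputs are unioned, mirroring the
    merge of a reference interactome with an organ-specific interaction map
    into one combined network.
    """
    merged = nx.Graph()
    merged.add_nodes_from(a.nodes)
    merged.add_nodes_from(b.nodes)
    for g in (a, b):
        for u, v, data in g.edges(data=True):
            src = data.get("sources")
            if merged.has_edge(u, v):
                if src:
                    merged.edges[u, v].setdefault("sources", set()).update(src)
            else:
                merged.add_edge(u, v, **({"sources": set(src)} if src else {}))
    return merged


def induce_subnetwork(network: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subnetwork induced by ``genes``: their mutual edges, isolated kept.

    Genes absent from the network are silently excluded (logged). Isolated
    members are retained as nodes — a differentially expressed gene with no
    qualifying partner is still part of the response network, it simply
    cannot join a connected module.
    """
    genes = set(genes)
    present = genes & set(network.nodes)
    missing = len(genes) - len(present)
    if missing:
        log.info("induce_subnetwork: %d query genes absent from network", missing)
    sub = nx.Graph()
    sub.add_nodes_from(present)
    sub.add_edges_from(
        (u, v, d) for u, v, d in network.edges(data=True)
        if u in present and v in present
    )
    return sub


def extension_network(
    network: nx.Graph, seeds: Iterable[str], levels: int = 1
) -> nx.Graph:
    """Grow ``seeds`` by ``levels`` rounds of neighbours, then induce.

    The node set is every node within graph distance ``levels`` of any seed
    (distances in ``network``); the edge set is induced on those nodes. With
    ``levels=0`` this is exactly :func:`induce_subnetwork`.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    seeds = set(seeds) & set(network.nodes)
    reach = set(seeds)
    for s in seeds:
        reach.update(nx.single_source_shortest_path_length(network, s, cutoff=levels))
    return induce_subnetwork(network, reach)


def find_hubs(network: nx.Graph, min_degree: int = 4) -> set[str]:
    """Nodes whose degree in ``network`` is at least ``min_degree``.

    The default of four interactions is the hub criterion used for the
    key-gene subnetworks.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    return {n for n, d in network.degree() if d >= min_degree}


def write_network(network: nx.Graph, path, format: str = "tsv_edges") -> None:
    """Write a network as a TSV edge list, SIF, or GraphML file.

    SIF uses the relation token ``pp`` (protein–protein). ``tsv_edges`` and
    ``sif`` round-trip exactly through :func:`read_edge_list` /
    :func:`read_sif`; isolated nodes are emitted as single-column lines in
    SIF only (the TSV dialect has no representation for them).
    """
    path = Path(path)
    if format == "tsv_edges":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(map(sorted, network.edges)):
                fh.write(f"{u}\t{v}\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(map(sorted, network.edges)):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(nx.isolates(network)):
                fh.write(f"{n}\n")
    elif format == "graphml":
        # GraphML cannot serialise set attributes; stringify source tags.
        g = nx.Graph()
        g.add_nodes_from(network.nodes)
        for u, v, d in network.edges(data=True):
            src = d.get("sources")
            g.add_edge(u, v, **({"sources": ",".join(sorted(src))} if src else {}))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_sif(path) -> nx.Graph:
    """Read a SIF file written by :func:`write_network`."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 1:
                g.add_node(fields[0])
            else:
                src, _rel, *targets = fields
                for t in targets:
                    if t != src:
                        g.add_edge(src, t)
    return g
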