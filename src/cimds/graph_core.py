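"""Graph data model and I/O.

Networks are simple undirected :class:`networkx.Graph` objects over string node
labels (protein symbols). Labels are case-sensitive opaque strings; no
identifier mapping is performed. Self-loops and duplicate/reversed edges are
canonicalised away on ingest because the dominating-set constraints assume a
simple graph.
"""

from __future__ import annotations

import logging
from collections import deque
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import EdgeListParseError, EmptyNetworkError, UnknownNodeError

logger = logging.getLogger(__name__)

Network = nx.Graph  # alias: the package-wide network container


def make_network(edges: Iterable[tuple[str, str]] = (),
                 singletons: Iterable[str] = ()) -> Network:
    """Build a canonical simple undirected network.

    Self-loops are dropped and duplicate/reversed edges merge. Singleton
    (degree-zero) nodes are permitted.
    """
    g = nx.Graph()
    dropped = 0
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            dropped += 1
            continue
        g.add_edge(u, v)
    g.add_nodes_from(str(n) for n in singletons)
    if dropped:
        logger.info("dropped %d self-loop(s) during canonicalisation", dropped)
    return g


def read_edge_list(path: str | Path, delimiter: str | None = None,
                   sif: bool = False) -> Network:
    """Read a network from a whitespace/tab-delimited edge list.

    Lines starting with ``#`` are comments. One-column lines declare singleton
    nodes. Two-column lines declare edges. With ``sif=True``, three-column
    SIF-style lines are accepted and the middle (interaction-type) column is
    ignored.

    Raises
    ------
    EdgeListParseError
        On a malformed line (wrong column count, empty label).
    EmptyNetworkError
        If the file contains no nodes at all.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    singletons: list[str] = []
    n_selfloops = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t.strip() for t in line.split(delimiter)]
            tokens = [t for t in tokens if t]
            if len(tokens) == 1:
                singletons.append(tokens[0])
            elif len(tokens) == 2:
                edges.append((tokens[0], tokens[1]))
            elif len(tokens) == 3 and sif:
                edges.append((tokens[0], tokens[2]))
            else:
                raise EdgeListParseError(
                    lineno, f"expected 2 columns, got {len(tokens)}: {line!r}")
            if len(tokens) in (2, 3) and edges and edges[-1][0] == edges[-1][1]:
                n_selfloops += 1
    net = make_network(edges, singletons)
    if n_selfloops:
        logger.info("%s: dropped %d self-loop line(s)", path.name, n_selfloops)
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError(f"{path}: no nodes found")
    return net


def write_edge_list(network: Network, path: str | Path) -> None:
    """Write a canonical edge list: endpoints lexicographic within a line,
    lines sorted; degree-zero nodes appear as one-column lines."""
    path = Path(path)
    lines = sorted(f"{min(u, v)}\t{max(u, v)}" for u, v in network.edges())
    lines += sorted(str(n) for n in network.nodes() if network.degree(n) == 0)
    path.write_text("".join(line + "\n" for line in lines))


def largest_connected_component(network: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components break toward the component containing
    the lexicographically smallest node label, so the result is deterministic.
    """
    if network.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot take the LCC of an empty network")
    comps = sorted(nx.connected_components(network),
                   key=lambda comp: (-len(comp), min(comp)))
    best = comps[0]
    return network.subgraph(best).copy()


def degree_centrality(network: Network) -> dict[str, int]:
    """Raw degree of every node (number of interacting partners)."""
    return {n: int(d) for n, d in network.degree()}


def betweenness_centrality(network: Network) -> dict[str, float]:
    """Unnormalised shortest-path betweenness.

    Endpoint nodes of a path are not counted as passed-through; contributions
    of a pair split equally among its equal-length shortest paths. Each
    unordered pair is counted once (undirected convention).
    """
    return nx.betweenness_centrality(network, normalized=False)


def boundary_ball(network: Network, v: str, ell: int) -> set[str]:
    """Nodes at shortest-path distance exactly ``ell`` from ``v``.

    ``ell=0`` returns ``{v}``; ``ell=1`` returns the neighbour set; distances
    beyond the component return the empty set.
    """
    if v not in network:
        raise UnknownNodeError(f"node {v!r} not in network")
    if ell < 0:
        raise ValueError("ell must be non-negative")
    if ell == 0:
        return {v}
    # BFS by levels, stopping once the requested depth is reached
    seen = {v}
    frontier = {v}
    for _ in range(ell):
        nxt = set()
        for u in frontier:
            for w in network[u]:
                if w not in seen:
                    seen.add(w)
                    nxt.add(w)
        frontier = nxt
        if not frontier:
            break
    return frontier


def bfs_levels(network: Network, v: str) -> Mapping[str, int]:
    """Shortest-path distance from ``v`` to every reachable node (plain BFS)."""
    if v not in network:
        raise UnknownNodeError(f"node {v!r} not in network")
    dist = {v: 0}
    q = deque([v])
    while q:
        u = q.popleft()
        for w in network[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist
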