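"""Interactome input/output and node-level topology metrics.

The interactome is an undirected protein–protein interaction network whose
nodes are UniProt-style accession strings.  All downstream features (diffusion
scores, module membership, safety-panel distances) are computed on this graph,
so loading is strict: self-loops are dropped, duplicate undirected edges are
merged, and by default the graph is restricted to its largest connected
component, since propagation and panel distances are undefined across
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: tokens that mark the first row of an edge list as a header, not an edge
_HEADER_TOKENS = {
    "protein",
    "protein1",
    "protein2",
    "accession",
    "source",
    "target",
    "node",
    "node1",
    "node2",
    "interactor_a",
    "interactor_b",
    "from",
    "to",
}


class GraphFormatError(ValueError):
    """Raised when an edge-list stream cannot be parsed."""


@dataclass
class InteractomeGraph:
    """Undirected protein interaction network.

    Wraps a :class:`networkx.Graph` whose nodes are accession strings,
    guaranteed free of self-loops and duplicate edges.
    """

    graph: nx.Graph
    label: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, accession: str) -> bool:
        return accession in self.graph

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("interactome must contain at least 2 nodes")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"interactome contains self-loops: {loops[:3]}")


@dataclass
class TopologyProfile:
    """Per-node degree centrality, betweenness and clustering coefficient.

    Degree centrality is degree/(n-1); betweenness is the normalized,
    endpoint-excluding Brandes variant; clustering coefficient is
    triangles/(k(k-1)/2), taken as 0 for degree < 2.  All three lie in [0, 1].
    """

    degree_centrality: Mapping[str, float]
    betweenness: Mapping[str, float]
    clustering_coefficient: Mapping[str, float]


def _iter_edge_rows(
    lines: Iterable[str], fmt: str
) -> Iterable[tuple[int, str, str]]:
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        tokens = [t.strip() for t in tokens if t.strip()]
        if lineno == 1 and any(t.lower() in _HEADER_TOKENS for t in tokens):
            continue
        if fmt == "edge-tsv":
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"line {lineno}: expected 2 columns, got {len(tokens)}"
                )
            yield lineno, tokens[0], tokens[1]
        elif fmt == "sif":
            # SIF rows are "A <relation> B [C D ...]"; relation is ignored.
            if len(tokens) < 3:
                raise GraphFormatError(
                    f"line {lineno}: SIF row needs >= 3 columns, got {len(tokens)}"
                )
            for other in tokens[2:]:
                yield lineno, tokens[0], other
        else:  # pragma: no cover - guarded by caller
            raise GraphFormatError(f"unknown format tag {fmt!r}")


def load_interactome(
    source: IO[str] | str | Iterable[str],
    fmt: str = "edge-tsv",
    label: str = "",
    largest_component: bool = True,
) -> InteractomeGraph:
    """Read an undirected interactome from an edge list.

    Parameters
    ----------
    source
        Path, open text stream, or iterable of lines.
    fmt
        ``"edge-tsv"`` (two whitespace/tab-separated accessions per row) or
        ``"sif"`` (``A <relation> B`` with the relation ignored).
    largest_component
        When true (default) the graph is restricted to its largest connected
        component; retained/dropped counts are logged.

    Self-loops are dropped with a warning; duplicate undirected edges are
    merged so the result is independent of row order.
    """
    if fmt not in ("edge-tsv", "sif"):
        raise GraphFormatError(f"unknown format tag {fmt!r}")

    close = False
    if isinstance(source, str):
        stream: Iterable[str] = open(source, "rt")
        close = True
    else:
        stream = source

    g = nx.Graph()
    n_loops = 0
    try:
        for lineno, a, b in _iter_edge_rows(stream, fmt):
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
    finally:
        if close:
            stream.close()  # type: ignore[union-attr]

    if n_loops:
        logger.warning("dropped %d self-loop row(s); nodes retained", n_loops)
    if g.number_of_nodes() == 0:
        raise GraphFormatError("no parsable rows: empty graph")

    if largest_component and g.number_of_nodes() > 0:
        components = list(nx.connected_components(g))
        if len(components) > 1:
            keep = max(components, key=lambda c: (len(c), min(c)))
            dropped = g.number_of_nodes() - len(keep)
            g = g.subgraph(keep).copy()
            logger.info(
                "restricted to largest component: kept %d nodes, dropped %d",
                len(keep),
                dropped,
            )
    return InteractomeGraph(graph=g, label=label)


def topology_profile(g: InteractomeGraph) -> TopologyProfile:
    """Compute degree centrality, betweenness and clustering coefficient."""
    g.validate()
    return TopologyProfile(
        degree_centrality=nx.degree_centrality(g.graph),
        betweenness=nx.betweenness_centrality(g.graph, normalized=True),
        clustering_coefficient=nx.clustering(g.graph),
    )


def bfs_distances(g: InteractomeGraph, source: str) -> dict[str, int]:
    """Hop distances from ``source`` to every reachable node (source at 0).

    Unreachable nodes are absent from the result.
    """
    if source not in g.graph:
        raise KeyError(f"source {source!r} not in graph")
    return dict(nx.single_source_shortest_path_length(g.graph, source))
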