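"""Interaction network over the selected genes: degrees, hubs, export.

The network is the induced undirected subgraph of a raw interaction pair
list on the selected genes: an edge is kept only when both endpoints are
selected, (A,B)/(B,A) and repeats collapse to one edge, and self-loops
are dropped.  A gene's degree is its number of interactions; genes with
degree strictly greater than a threshold (default 10) are flagged as
hubs.  Exports are Cytoscape-compatible (SIF, GraphML) plus a plain TSV
edge list, all in deterministic lexicographic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .data_io import InteractionList

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    hub_threshold: int = 10
    direction_of_regulation: dict[str, str] = field(default_factory=dict)

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def hub_flags(self) -> dict[str, bool]:
        return {g: d > self.hub_threshold for g, d in self.graph.degree()}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    selected: Iterable[str],
    interactions: InteractionList,
    hub_threshold: int = 10,
    direction_of_regulation: Mapping[str, str] | None = None,
    include_isolated: bool = False,
) -> InteractionNetwork:
    """Induced subgraph of the interaction list on the selected genes.

    Duplicate edges in either orientation collapse; self-loops are
    dropped with a logged count.  By default only genes participating in
    at least one retained edge become nodes; ``include_isolated`` adds
    every selected gene as a node.
    """
    selected = set(selected)
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(selected)
    n_self = 0
    for a, b in interactions.edges:
        if a == b:
            if a in selected:
                n_self += 1
            continue
        if a in selected and b in selected:
            g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loops", n_self)
    dirmap = dict(direction_of_regulation or {})
    return InteractionNetwork(g, hub_threshold, dirmap)


def find_hubs(
    net: InteractionNetwork, threshold: int | None = None
) -> list[tuple[str, int]]:
    """Genes with degree strictly above the threshold, sorted by degree
    descending then gene id ascending."""
    if threshold is None:
        threshold = net.hub_threshold
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hubs = [(g, d) for g, d in net.graph.degree() if d > threshold]
    return sorted(hubs, key=lambda gd: (-gd[1], gd[0]))


def _sorted_edges(net: InteractionNetwork) -> list[tuple[str, str]]:
    return sorted(tuple(sorted(e)) for e in net.graph.edges())


def export_network(
    net: InteractionNetwork, path: str | Path, fmt: str = "sif"
) -> None:
    """Write the network as SIF, GraphML, or a TSV edge list.

    SIF lines read ``geneA pp geneB``; GraphML carries per-node degree,
    hub flag, and the up/down regulation label when provided.  Node and
    edge order is lexicographic so output bytes are deterministic.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in _sorted_edges(net):
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        deg = net.degree
        hubs = net.hub_flags
        for node in sorted(net.graph.nodes()):
            attrs = {"degree": deg[node], "hub": bool(hubs[node])}
            if node in net.direction_of_regulation:
                attrs["regulation"] = net.direction_of_regulation[node]
            g.add_node(node, **attrs)
        g.add_edges_from(_sorted_edges(net))
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in _sorted_edges(net):
                fh.write(f"{a}\t{b}\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (use sif, graphml, or tsv)")


def import_network_tsv(path: str | Path, hub_threshold: int = 10) -> InteractionNetwork:
    """Read a TSV edge list written by :func:`export_network` back into a
    network (round-trip counterpart)."""
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")
            edges.append((a, b))
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(g, hub_threshold)


def hubs_frame(net: InteractionNetwork, threshold: int | None = None):
    import pandas as pd

    return pd.DataFrame(find_hubs(net, threshold), columns=["gene", "degree"])
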