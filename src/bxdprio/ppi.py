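"""Focal-gene interaction neighborhoods from a PPI edge list.

Primary interactors are direct neighbors of the focal gene; secondary
interactors sit at shortest-path distance exactly 2.  Node degree for
hub ranking is computed, by default, within the subgraph induced by the
focal gene and both interactor tiers — mirroring hub scoring applied to
the displayed ego network rather than the full input graph.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

__all__ = ["InteractorSet", "read_edge_list", "ego_interactors", "high_connectivity"]


def read_edge_list(path, focal: str | None = None) -> nx.Graph:
    """Undirected simple graph from a two-column whitespace/tab TSV.

    Duplicate and reversed pairs collapse; self-loops are dropped with a
    warning reporting their count.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s) from {path}")
    if focal is not None:
        graph.graph["focal"] = focal
    return graph


@dataclass(frozen=True)
class InteractorSet:
    focal: str
    primary: frozenset
    secondary: frozenset
    degrees: dict  # symbol -> degree within the induced ego subgraph

    @property
    def members(self) -> frozenset:
        return self.primary | self.secondary


def ego_interactors(
    graph: nx.Graph, focal: str | None = None, full_graph_degree: bool = False
) -> InteractorSet:
    """Primary/secondary interactors of the focal gene with their degrees.

    Degrees are computed within the subgraph induced by
    {focal} | primary | secondary unless ``full_graph_degree``.
    """
    if focal is None:
        focal = graph.graph.get("focal")
    if focal is None or focal not in graph:
        raise ValueError(f"focal gene {focal!r} not in graph")
    dist = nx.single_source_shortest_path_length(graph, focal, cutoff=2)
    primary = frozenset(g for g, d in dist.items() if d == 1)
    secondary = frozenset(g for g, d in dist.items() if d == 2)
    members = {focal} | primary | secondary
    source = graph if full_graph_degree else graph.subgraph(members)
    degrees = {g: int(source.degree(g)) for g in members}
    return InteractorSet(focal=focal, primary=primary, secondary=secondary, degrees=degrees)


def high_connectivity(interactors: InteractorSet, min_degree: int = 5) -> list[str]:
    """Interactors (focal excluded) with degree >= min_degree,
    sorted by degree descending then symbol."""
    hubs = [
        (g, d)
        for g, d in interactors.degrees.items()
        if g != interactors.focal and d >= min_degree
    ]
    hubs.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in hubs]
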