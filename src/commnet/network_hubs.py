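"""PPI induced subgraphs and hub ranking by node degree."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datamodel import EdgeList, ValidationError


@dataclass
class GeneGraph:
    """Undirected gene graph; isolated query genes are retained at degree 0."""

    graph: nx.Graph

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def degree(self) -> dict:
        return dict(self.graph.degree())


def induced_subgraph(ppi: EdgeList, genes) -> GeneGraph:
    """Subgraph of the PPI over ``genes``; members without any PPI edge are
    kept as isolated nodes so the report shows unsupported screen genes."""
    genes = set(genes)
    if not genes:
        raise ValidationError("empty gene set")
    g = nx.Graph()
    g.add_nodes_from(genes)
    for (a, b), score in ppi.edges.items():
        if a in genes and b in genes:
            g.add_edge(a, b, **({} if score is None else {"score": score}))
    return GeneGraph(g)


def rank_hubs(graph: GeneGraph, k: int = 15):
    """Top-k genes by degree (ties by symbol); returns (list, degree table)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    deg = graph.degree()
    table = pd.DataFrame(
        sorted(deg.items(), key=lambda it: (-it[1], it[0])),
        columns=["gene", "degree"],
    )
    if k > len(table):
        warnings.warn(f"k={k} exceeds {len(table)} nodes; returning all")
        k = len(table)
    return table["gene"].head(k).tolist(), table
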