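"""Bipartite compound–target (C-T) and target–pathway (T-P) networks.

Networks are undirected bipartite graphs with typed sides; isolated nodes
are excluded by construction, so the node count always equals the number
of entities participating in at least one edge.  Degree is the only
topological statistic used: the side means are edge count divided by side
size (for the C-T network, edges per compound and edges per target).

Node and edge insertion order is deterministic (sorted), so repeated
exports of the same network are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .data_io import CompoundTargetEdge, GeneSetCollection, ValidationError

log = logging.getLogger("netpharm")

__all__ = [
    "BipartiteNetwork",
    "DegreeReport",
    "build_ct_network",
    "build_tp_network",
    "degree_statistics",
    "export_network",
    "read_graphml_network",
]


@dataclass
class BipartiteNetwork:
    """Typed two-sided graph; ``graph`` is an undirected networkx Graph
    whose nodes carry a ``kind`` attribute (``a_type`` or ``b_type``)."""

    graph: nx.Graph
    side_a: frozenset
    side_b: frozenset
    a_type: str
    b_type: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DegreeReport:
    """Per-node degrees plus side-mean summaries and a ranked hub list.

    ``mean_degree_side_a`` is n_edges / |side_a| (and likewise for b);
    hubs are ranked by degree descending, ties by node id ascending.
    """

    degrees: dict
    n_nodes: int
    n_edges: int
    mean_degree_side_a: float
    mean_degree_side_b: float
    hubs: list  # [(node, degree), ...]

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree_side_a": round(self.mean_degree_side_a, 2),
            "mean_degree_side_b": round(self.mean_degree_side_b, 2),
        }


def _build(pairs, a_type: str, b_type: str) -> BipartiteNetwork:
    """Assemble a bipartite graph from (a, b) pairs, deterministically."""
    pairs = sorted(set(pairs))
    side_a = sorted({a for a, _ in pairs})
    side_b = sorted({b for _, b in pairs})
    overlap = set(side_a) & set(side_b)
    if overlap:
        raise ValidationError(f"nodes appear on both sides: {sorted(overlap)[:5]}")
    g = nx.Graph()
    for a in side_a:
        g.add_node(a, kind=a_type, bipartite=0)
    for b in side_b:
        g.add_node(b, kind=b_type, bipartite=1)
    g.add_edges_from(pairs)
    return BipartiteNetwork(
        graph=g,
        side_a=frozenset(side_a),
        side_b=frozenset(side_b),
        a_type=a_type,
        b_type=b_type,
    )


def build_ct_network(
    final_compounds: Iterable[str],
    overlap_genes: Iterable[str],
    edges: Iterable[CompoundTargetEdge],
) -> BipartiteNetwork:
    """Compound–target network over the final compounds and overlap genes.

    Only edges with both endpoints qualifying are kept; compounds or genes
    with no qualifying edge are absent from the node set.
    """
    compounds = frozenset(final_compounds)
    genes = frozenset(overlap_genes)
    pairs = [
        (e.mol_id, e.gene_symbol)
        for e in edges
        if e.mol_id in compounds and e.gene_symbol in genes
    ]
    return _build(pairs, a_type="compound", b_type="target")


def build_tp_network(
    overlap_genes: Iterable[str],
    retained_pathways: Iterable,
    collection: GeneSetCollection,
) -> BipartiteNetwork:
    """Target–pathway network: edge (gene, pathway) iff the overlap gene
    belongs to an FDR-retained pathway.  Genes in no retained pathway are
    excluded (they do not map onto the pathway view)."""
    genes = frozenset(overlap_genes)
    retained_ids = {r.set_id for r in retained_pathways if getattr(r, "retained", True)}
    by_id = {gs.set_id: gs for gs in collection.sets}
    pairs = []
    for set_id in retained_ids:
        gs = by_id.get(set_id)
        if gs is None:
            log.warning("retained pathway %r not found in collection", set_id)
            continue
        for gene in gs.genes & genes:
            pairs.append((gene, set_id))
    return _build(pairs, a_type="target", b_type="pathway")


def degree_statistics(net: BipartiteNetwork) -> DegreeReport:
    """Degree map, side means and ranked hubs; an empty network yields a
    zeroed report."""
    degrees = {node: int(deg) for node, deg in net.graph.degree()}
    n_edges = net.n_edges
    mean_a = n_edges / len(net.side_a) if net.side_a else 0.0
    mean_b = n_edges / len(net.side_b) if net.side_b else 0.0
    hubs = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return DegreeReport(
        degrees=degrees,
        n_nodes=net.n_nodes,
        n_edges=n_edges,
        mean_degree_side_a=mean_a,
        mean_degree_side_b=mean_b,
        hubs=hubs,
    )


def _ordered_nodes(net: BipartiteNetwork):
    return sorted(net.graph.nodes(data=True), key=lambda nd: (nd[1].get("kind", ""), nd[0]))


def export_network(net: BipartiteNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, SIF or a TSV edge list.

    GraphML carries ``kind`` and ``degree`` node attributes.  Node and edge
    order is (type, id)-sorted, so identical networks export to identical
    bytes.
    """
    path = Path(path)
    if fmt == "graphml":
        out = nx.Graph()
        degs = dict(net.graph.degree())
        for node, data in _ordered_nodes(net):
            out.add_node(node, kind=data.get("kind", ""), degree=int(degs[node]))
        for a, b in sorted(net.graph.edges()):
            out.add_edge(*sorted((a, b)))
        nx.write_graphml(out, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for a, b in sorted(sorted(edge) for edge in net.graph.edges()):
                fh.write(f"{a}\tinteracts\t{b}\n")
    elif fmt == "tsv":
        kinds = nx.get_node_attributes(net.graph, "kind")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\ttarget\tsource_kind\ttarget_kind\n")
            for a, b in sorted(sorted(edge) for edge in net.graph.edges()):
                fh.write(f"{a}\t{b}\t{kinds.get(a, '')}\t{kinds.get(b, '')}\n")
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def read_graphml_network(path, a_type: str, b_type: str) -> BipartiteNetwork:
    """Re-import a GraphML export (round-trip helper)."""
    g = nx.read_graphml(path)
    kinds = nx.get_node_attributes(g, "kind")
    side_a = frozenset(n for n, kind in kinds.items() if kind == a_type)
    side_b = frozenset(n for n, kind in kinds.items() if kind == b_type)
    return BipartiteNetwork(graph=g, side_a=side_a, side_b=side_b, a_type=a_type, b_type=b_type)
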