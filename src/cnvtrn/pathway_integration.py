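"""Overlay the CNV-aware regulatory network on signaling-pathway graphs.

Pathway nodes that carry copy-number variation, or that are regulated by a
CNV-TF in the network, are the *overlapped* nodes.  Their 1-hop pathway
neighborhood is expanded, and the integrated graph merges the pathway
edges of that neighborhood with the regulatory edges incident to
overlapped nodes, keeping the origin of every edge as an attribute.
The per-pathway disturbance fraction quantifies how much of a pathway is
touched by copy-number variation directly or through its regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .cnv_profiling import CnvCallSet
from .io_formats import DirectedEdge
from .trn_inference import Trn

__all__ = [
    "PathwayGraph",
    "find_overlap_nodes",
    "expand_neighbors",
    "merge_networks",
    "disturbance_fraction",
    "cnv_tf_targets",
]


@dataclass
class PathwayGraph:
    """A named directed pathway graph over gene ids."""

    name: str
    edges: list[DirectedEdge]
    extra_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(sorted(self.extra_nodes))
        for e in self.edges:
            self._graph.add_edge(e.source, e.target, label=e.label)

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @classmethod
    def from_edge_list(
        cls, name: str, edges: list[DirectedEdge], extra_nodes: set[str] | None = None
    ) -> "PathwayGraph":
        return cls(name=name, edges=list(edges), extra_nodes=set(extra_nodes or ()))


def cnv_tf_targets(trn: Trn, cnv_call: CnvCallSet) -> set[str]:
    """Genes regulated by a CNV-TF in the retained network."""
    return {e.target_id for e in trn.edges if e.tf_id in cnv_call.cnv_tfs}


def find_overlap_nodes(trn: Trn, cnv_call: CnvCallSet, pathway: PathwayGraph) -> set[str]:
    """Pathway nodes that are CNV-genes or targets of a CNV-TF in the TRN."""
    disturbed = cnv_call.cnv_genes | cnv_tf_targets(trn, cnv_call)
    return pathway.nodes & disturbed


def expand_neighbors(pathway: PathwayGraph, overlapped: set[str]) -> nx.DiGraph:
    """Induced pathway subgraph on overlapped nodes plus 1-hop neighbors.

    Neighbors are taken in both edge directions.
    """
    if not overlapped <= pathway.nodes:
        raise ValueError("overlapped nodes must lie within the pathway")
    g = pathway.graph
    keep = set(overlapped)
    for n in overlapped:
        keep.update(g.successors(n))
        keep.update(g.predecessors(n))
    return g.subgraph(keep).copy()


def merge_networks(
    trn: Trn,
    cnv_call: CnvCallSet,
    pathways: list[PathwayGraph],
    is_tf: dict[str, bool] | None = None,
) -> nx.MultiDiGraph:
    """Build the integrated network around overlapped nodes.

    TRN edges incident to at least one overlapped node are merged with each
    pathway's expanded-neighborhood edges.  The same gene pair appearing in
    both sources yields two attributed parallel edges.  Node attributes:
    ``role`` (tf/gene), ``cnv_status`` (cnv/non_cnv), ``origin``
    (trn/pathway/both); edge attributes: ``origin`` and, for pathway edges,
    ``pathway``.
    """
    gene_ids = trn.genes | cnv_call.cnv_genes | {n for p in pathways for n in p.nodes}
    for p in pathways:
        if p.name in gene_ids:
            raise ValueError(f"pathway name {p.name!r} collides with a gene id")

    out = nx.MultiDiGraph()
    overlapped_all: set[str] = set()
    trn_nodes: set[str] = set()
    pathway_nodes: set[str] = set()

    for p in pathways:
        overlapped = find_overlap_nodes(trn, cnv_call, p)
        overlapped_all |= overlapped
        if not overlapped:
            continue
        sub = expand_neighbors(p, overlapped)
        for u, v, data in sub.edges(data=True):
            out.add_edge(u, v, origin="pathway", pathway=p.name, label=data.get("label"))
            pathway_nodes.update((u, v))
        pathway_nodes.update(sub.nodes)
        for n in sub.nodes:
            if n not in out:
                out.add_node(n)

    for e in trn.edges:
        if e.tf_id in overlapped_all or e.target_id in overlapped_all:
            out.add_edge(e.tf_id, e.target_id, origin="trn", clr=e.clr)
            trn_nodes.update((e.tf_id, e.target_id))

    for n in out.nodes:
        role = "tf" if (is_tf or {}).get(n, False) else "gene"
        origin = (
            "both"
            if n in trn_nodes and n in pathway_nodes
            else "trn" if n in trn_nodes else "pathway"
        )
        out.nodes[n].update(
            role=role,
            cnv_status="cnv" if n in cnv_call.cnv_genes else "non_cnv",
            origin=origin,
            overlapped=bool(n in overlapped_all),
        )
    return out


def disturbance_fraction(pathway: PathwayGraph, cnv_call: CnvCallSet, trn: Trn) -> float:
    """Fraction of pathway genes that are CNV-genes or CNV-TF targets."""
    nodes = pathway.nodes
    if not nodes:
        raise ValueError(f"pathway {pathway.name} is empty")
    disturbed = nodes & (cnv_call.cnv_genes | cnv_tf_targets(trn, cnv_call))
    return len(disturbed) / len(nodes)
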