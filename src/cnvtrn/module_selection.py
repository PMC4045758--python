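"""Select CNV-related regulatory modules and tally network node/edge types.

A regulatory module is one TF together with all of its first-layer targets
in the retained network.  Two one-sided Fisher screens decide which
modules enter the CNV-aware network:

* pathway enrichment of the module's genes against the expressed-gene
  background (the module must have a clear biological function), and
* CNV-gene enrichment against the network-gene background, unless the
  module's TF itself lies in a CNV region.

Benjamini-Hochberg correction is applied within each screen; a module is
kept iff it passes the pathway screen AND is either CNV-TF regulated or
CNV-gene enriched, which also determines its type label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cnv_profiling import CnvCallSet
from .io_formats import GeneSetCollection
from .trn_inference import Trn

__all__ = [
    "RegulatoryModule",
    "EnrichmentResult",
    "NetworkTypeTally",
    "extract_modules",
    "fisher_enrichment",
    "bh_fdr",
    "select_cnv_modules",
    "tally_types",
    "EDGE_TYPES",
    "NODE_TYPES",
]

CNV_TF_ONLY = "cnv_tf_only"
CNV_GENE_ONLY = "cnv_gene_only"
BOTH = "both"

NODE_TYPES = ["CNV-TF", "non-CNV-TF", "CNV-gene", "non-CNV-gene"]
EDGE_TYPES = [
    "CNV-TF to CNV-TF",
    "CNV-TF to non-CNV-TF",
    "non-CNV-TF to non-CNV-TF",
    "CNV-TF to CNV-gene",
    "CNV-TF to non-CNV-gene",
    "non-CNV-TF to CNV-gene",
    "non-CNV-TF to non-CNV-gene",
]


@dataclass
class EnrichmentResult:
    tf_id: str
    set_name: str
    a: int  # module ∩ set
    b: int  # module \ set
    c: int  # set \ module (within background)
    d: int  # rest of background
    p_value: float
    q_value: float | None = None


@dataclass
class RegulatoryModule:
    tf_id: str
    targets: set[str]
    module_type: str | None = None
    kegg_enrichment: list[EnrichmentResult] = field(default_factory=list)
    cnv_enrichment: EnrichmentResult | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"module {self.tf_id} has no targets")

    @property
    def genes(self) -> set[str]:
        """TF plus first-layer targets."""
        return self.targets | {self.tf_id}

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class NetworkTypeTally:
    node_counts: dict[str, int]
    edge_counts: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return sum(self.node_counts.values())

    @property
    def n_edges(self) -> int:
        return sum(self.edge_counts.values())


# ---------------------------------------------------------------------------


def extract_modules(trn: Trn) -> list[RegulatoryModule]:
    """One module per TF with at least one retained edge."""
    return [
        RegulatoryModule(tf_id=tf, targets=set(targets))
        for tf, targets in sorted(trn.modules.items())
        if targets
    ]


def fisher_enrichment(
    module_genes: set[str], gene_set: frozenset[str] | set[str], background: set[str]
) -> tuple[int, int, int, int, float]:
    """One-sided (over-representation) Fisher exact test.

    Counts are taken within ``background``: a = |module ∩ set|,
    b = |module \\ set|, c = |set \\ module|, d = the rest.  Returns
    (a, b, c, d, p) with p the upper hypergeometric tail P(K >= a).
    """
    if not background:
        raise ValueError("empty background")
    extra = module_genes - background
    if extra:
        raise ValueError(f"module genes outside background: {sorted(extra)[:5]}")
    set_in_bg = set(gene_set) & background
    a = len(module_genes & set_in_bg)
    b = len(module_genes) - a
    c = len(set_in_bg) - a
    d = len(background) - a - b - c
    n_bg = len(background)
    # P(X >= a), X ~ Hypergeom(N=n_bg, K=|set|, n=|module|)
    p = float(hypergeom.sf(a - 1, n_bg, a + c, a + b))
    return a, b, c, d, min(max(p, np.nextafter(0, 1)), 1.0)


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_cnv_modules(
    modules: list[RegulatoryModule],
    gene_sets: GeneSetCollection,
    cnv_call: CnvCallSet,
    network_genes: set[str],
    expressed_genes: set[str],
    fdr: float = 0.05,
) -> list[RegulatoryModule]:
    """Apply both enrichment screens and return typed CNV-related modules.

    Pathway enrichment uses ``expressed_genes`` as background, CNV-gene
    enrichment uses ``network_genes``; BH is applied within each screen.
    A module survives iff it has >= 1 pathway set at q < ``fdr`` AND
    (its TF is a CNV-TF OR its CNV-gene enrichment has q < ``fdr``).
    """
    if not modules:
        return []
    kegg_records: list[EnrichmentResult] = []
    for mod in modules:
        genes = mod.genes & expressed_genes
        if mod.genes - expressed_genes:
            raise ValueError(
                f"module {mod.tf_id} has genes outside the expressed background"
            )
        for name in sorted(gene_sets):
            a, b, c, d, p = fisher_enrichment(genes, gene_sets[name].genes, expressed_genes)
            kegg_records.append(EnrichmentResult(mod.tf_id, name, a, b, c, d, p))
    if kegg_records:
        qs = bh_fdr([r.p_value for r in kegg_records])
        for r, q in zip(kegg_records, qs):
            r.q_value = float(q)

    cnv_records: list[EnrichmentResult] = []
    for mod in modules:
        if mod.genes - network_genes:
            raise ValueError(
                f"module {mod.tf_id} has genes outside the network background"
            )
        a, b, c, d, p = fisher_enrichment(mod.genes, cnv_call.cnv_genes, network_genes)
        cnv_records.append(EnrichmentResult(mod.tf_id, "CNV-genes", a, b, c, d, p))
    qs = bh_fdr([r.p_value for r in cnv_records])
    for r, q in zip(cnv_records, qs):
        r.q_value = float(q)
    cnv_by_tf = {r.tf_id: r for r in cnv_records}

    kegg_by_tf: dict[str, list[EnrichmentResult]] = {}
    for r in kegg_records:
        kegg_by_tf.setdefault(r.tf_id, []).append(r)

    selected: list[RegulatoryModule] = []
    for mod in modules:
        kegg_hits = [r for r in kegg_by_tf.get(mod.tf_id, []) if r.q_value < fdr]
        if not kegg_hits:
            continue
        cnv_rec = cnv_by_tf[mod.tf_id]
        tf_is_cnv = mod.tf_id in cnv_call.cnv_tfs
        gene_enriched = cnv_rec.q_value < fdr
        if not (tf_is_cnv or gene_enriched):
            continue
        if tf_is_cnv and gene_enriched:
            mtype = BOTH
        elif tf_is_cnv:
            mtype = CNV_TF_ONLY
        else:
            mtype = CNV_GENE_ONLY
        selected.append(
            RegulatoryModule(
                tf_id=mod.tf_id,
                targets=set(mod.targets),
                module_type=mtype,
                kegg_enrichment=sorted(kegg_hits, key=lambda r: r.p_value),
                cnv_enrichment=cnv_rec,
            )
        )
    return selected


def tally_types(
    edges: list[tuple[str, str]],
    is_tf: dict[str, bool],
    cnv_call: CnvCallSet,
) -> NetworkTypeTally:
    """Partition nodes into 4 classes and edges into 7 classes.

    A node is a TF iff its annotation flags it so, regardless of whether it
    appears as a regulator or a target; CNV status comes from the call set.
    TF->TF edges are classed by the unordered pair of CNV statuses (the
    mixed class covers both orientations); TF->gene edges by the ordered
    (source, target) statuses.
    """
    nodes = {n for e in edges for n in e}
    node_counts = dict.fromkeys(NODE_TYPES, 0)
    node_type: dict[str, str] = {}
    for n in sorted(nodes):
        if n not in is_tf:
            raise KeyError(f"node {n} has no TF/gene role annotation")
        cnv = n in cnv_call.cnv_genes
        t = ("CNV-" if cnv else "non-CNV-") + ("TF" if is_tf[n] else "gene")
        node_type[n] = t
        node_counts[t] += 1

    edge_counts = dict.fromkeys(EDGE_TYPES, 0)
    for u, v in edges:
        ut, vt = node_type[u], node_type[v]
        if ut.endswith("TF") and vt.endswith("TF"):
            n_cnv = (ut == "CNV-TF") + (vt == "CNV-TF")
            key = EDGE_TYPES[2 - n_cnv]  # 2 CNV -> idx 0, 1 -> idx 1, 0 -> idx 2
        else:
            key = f"{ut} to {vt}"
        edge_counts[key] += 1
    return NetworkTypeTally(node_counts=node_counts, edge_counts=edge_counts)
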