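"""CERN construction: GRN denoising, edge duplication, directed
intersection, centralities, and two-condition node overlap.

The co-expressed regulatory network (CERN) keeps a TF->target edge only
when the corresponding gene pair is also a co-expression edge. Because
co-expression is undirected, its edges are first duplicated into both
ordered directions; the intersection with the directed GRN then preserves
TF->target directionality. Each retained edge carries both lines of
evidence: the GRN importance score and the co-expression adjacency weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from .model import (
    CERN,
    CoexpressionNetwork,
    CuratedTFNetwork,
    RegulatoryNetwork,
    TFList,
    UNASSIGNED_MODULE,
)

logger = logging.getLogger("cernet")

#: Node-class display colours in the combined two-condition network.
OVERLAP_CLASS_COLORS = {"shared": "yellow", "unique_a": "green", "unique_b": "gold"}


@dataclass
class CentralityRecord:
    gene: str
    in_degree: int
    out_degree: int
    betweenness: float
    closeness: float
    pagerank: float


@dataclass
class OverlapReport:
    shared: Set[str]
    unique_a: Set[str]
    unique_b: Set[str]
    combined_edges: Dict[Tuple[str, str], Dict[str, object]]
    class_of: Dict[str, str]
    condition_a: str = ""
    condition_b: str = ""

    @property
    def n_combined_nodes(self) -> int:
        return len(self.shared) + len(self.unique_a) + len(self.unique_b)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "class": cls,
                "color": OVERLAP_CLASS_COLORS[cls],
            }
            for g, cls in sorted(self.class_of.items())
        ]
        return pd.DataFrame(rows)


def filter_grn(
    grn: RegulatoryNetwork,
    curated: Optional[CuratedTFNetwork] = None,
    enabled: bool = True,
) -> RegulatoryNetwork:
    """Keep only GRN edges present in the curated TF->target network.

    With ``enabled=False`` (or no curated network supplied) the GRN passes
    through unchanged — inferred edges are then used as-is.
    """
    if not enabled:
        return grn
    if curated is None:
        logger.info("no curated TF-target network supplied; GRN not filtered")
        return grn
    kept = {pair: imp for pair, imp in grn.edges.items() if pair in curated.pairs}
    if not kept and grn.edges:
        logger.warning(
            "curated filter removed all %d GRN edges (%s)",
            grn.n_edges,
            grn.condition_name,
        )
    else:
        logger.info(
            "curated filter: %d of %d GRN edges retained (%s)",
            len(kept),
            grn.n_edges,
            grn.condition_name,
        )
    return RegulatoryNetwork(kept, condition_name=grn.condition_name)


def duplicate_edges(
    coexp: CoexpressionNetwork,
) -> Dict[Tuple[str, str], float]:
    """Duplicate each undirected pair {A, B} into (A, B) and (B, A).

    Both ordered copies carry the pair's adjacency weight, so the directed
    GRN can be intersected regardless of which direction it asserts.
    """
    directed: Dict[Tuple[str, str], float] = {}
    for (a, b), w in coexp.edges.items():
        directed[(a, b)] = w
        directed[(b, a)] = w
    return directed


def merge_reg_coexp(
    grn: RegulatoryNetwork,
    coexp: CoexpressionNetwork,
    tf_list: Optional[TFList] = None,
) -> CERN:
    """Intersect the (filtered) GRN with the duplicated co-expression edges.

    A TF->target edge survives iff its unordered gene pair is co-expressed;
    the TF->target direction comes from the GRN. Nodes are annotated with
    their module colour ("grey" when absent from the partition) and an
    ``is_tf`` flag derived from the retained edges themselves; when a TF
    list is supplied, membership is recorded as ``in_tf_list``.
    """
    edges: Dict[Tuple[str, str], Dict[str, float]] = {}
    for (tf, tg), imp in grn.edges.items():
        if coexp.has_pair(tf, tg):
            edges[(tf, tg)] = {
                "importance": imp,
                "coexp_weight": coexp.weight(tf, tg),
            }
    tf_nodes = {tf for tf, _ in edges}
    annotations: Dict[str, Dict[str, object]] = {}
    for tf, tg in edges:
        for node in (tf, tg):
            if node not in annotations:
                annotations[node] = {
                    "module": coexp.partition.label_of(node),
                    "is_tf": node in tf_nodes,
                }
                if tf_list is not None:
                    annotations[node]["in_tf_list"] = node in tf_list
    logger.info(
        "CERN (%s): %d of %d GRN edges co-expressed; %d nodes",
        coexp.condition_name,
        len(edges),
        grn.n_edges,
        len(annotations),
    )
    return CERN(edges, annotations, condition_name=coexp.condition_name)


def network_centrality(cern: CERN) -> List[CentralityRecord]:
    """Directed centralities for every CERN node.

    * in/out degree — raw counts;
    * betweenness — directed, normalized by (n-1)(n-2);
    * closeness — incoming-distance convention (how quickly a node is
      reached from the rest of the network), networkx default;
    * pagerank — damping 0.85, values sum to 1.

    Scores are also written into ``cern.node_annotations`` in place.
    """
    if not cern.nodes:
        return []
    g = nx.DiGraph()
    g.add_nodes_from(cern.nodes)
    g.add_edges_from(cern.edges)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g)  # incoming distances
    pagerank = nx.pagerank(g, alpha=0.85)
    records = [
        CentralityRecord(
            gene=node,
            in_degree=g.in_degree(node),
            out_degree=g.out_degree(node),
            betweenness=betweenness[node],
            closeness=closeness[node],
            pagerank=pagerank[node],
        )
        for node in sorted(g.nodes)
    ]
    for rec in records:
        ann = cern.node_annotations[rec.gene]
        ann.update(
            in_degree=rec.in_degree,
            out_degree=rec.out_degree,
            betweenness=rec.betweenness,
            closeness=rec.closeness,
            pagerank=rec.pagerank,
        )
    return records


def centrality_frame(records: List[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "in_degree": r.in_degree,
                "out_degree": r.out_degree,
                "betweenness": r.betweenness,
                "closeness": r.closeness,
                "pagerank": r.pagerank,
            }
            for r in records
        ]
    )


def network_overlap(cern_a: CERN, cern_b: CERN) -> OverlapReport:
    """Classify nodes of two CERNs as shared / unique and union the edges.

    Shared nodes are drawn yellow, nodes unique to the first condition
    green, unique to the second gold. The combined edge set is the ordered
    union; when both conditions carry the same edge, each side's attributes
    are kept under source-tagged keys.
    """
    nodes_a, nodes_b = cern_a.nodes, cern_b.nodes
    shared = nodes_a & nodes_b
    unique_a = nodes_a - nodes_b
    unique_b = nodes_b - nodes_a
    class_of: Dict[str, str] = {}
    for g in shared:
        class_of[g] = "shared"
    for g in unique_a:
        class_of[g] = "unique_a"
    for g in unique_b:
        class_of[g] = "unique_b"

    name_a = cern_a.condition_name or "a"
    name_b = cern_b.condition_name or "b"
    combined: Dict[Tuple[str, str], Dict[str, object]] = {}
    for source, cern in ((name_a, cern_a), (name_b, cern_b)):
        for pair, attrs in cern.edges.items():
            entry = combined.setdefault(pair, {"sources": []})
            entry["sources"].append(source)
            for key, val in attrs.items():
                entry[f"{key}_{source}"] = val
    for entry in combined.values():
        entry["sources"] = ",".join(entry["sources"])

    logger.info(
        "node overlap: %d shared, %d unique to %s, %d unique to %s "
        "(combined: %d nodes, %d edges)",
        len(shared), len(unique_a), name_a, len(unique_b), name_b,
        len(shared) + len(unique_a) + len(unique_b), len(combined),
    )
    return OverlapReport(
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        combined_edges=combined,
        class_of=class_of,
        condition_a=name_a,
        condition_b=name_b,
    )


def combined_cern(report: OverlapReport, cern_a: CERN, cern_b: CERN) -> CERN:
    """Materialize the combined two-condition network for export."""
    annotations: Dict[str, Dict[str, object]] = {}
    for cern in (cern_a, cern_b):
        for node, attrs in cern.node_annotations.items():
            annotations.setdefault(node, {}).update(
                {k: v for k, v in attrs.items() if k in ("module", "is_tf")}
            )
    for node, cls in report.class_of.items():
        annotations[node]["overlap_class"] = cls
        annotations[node]["color"] = OVERLAP_CLASS_COLORS[cls]
    name = f"{report.condition_a}+{report.condition_b}"
    return CERN(report.combined_edges, annotations, condition_name=name)
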