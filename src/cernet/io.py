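"""Readers and writers for the external formats the pipeline touches.

Input formats
-------------
* WGCNA node/edge tables as written by ``exportNetworkToCytoscape``
  (tab-separated, headers ``nodeName``/``nodeAttr`` and
  ``fromNode``/``toNode``/``weight``); unknown headers fall back to
  positional interpretation with a warning.
* GRN edge lists as written by GRNBoost2 (tab-separated ``TF``, ``target``,
  ``importance``).
* TF lists as CSV with a protein-id column.
* Curated TF->target pair lists (two columns, optional source column).

Output formats
--------------
* GMT (gene matrix transposed): one module per line — label, description,
  member genes, tab-separated.
* GraphML for CERNs (directed; node attributes carry module colour, TF flag
  and centralities; edge attributes carry importance and co-expression
  weight).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx
import pandas as pd

from .model import (
    CERN,
    CoexpressionNetwork,
    CuratedTFNetwork,
    ModulePartition,
    RegulatoryNetwork,
    TFList,
    UNASSIGNED_MODULE,
    normalize_gene_id,
    normalize_module_label,
    undirected_key,
)

logger = logging.getLogger("cernet")


class FormatError(ValueError):
    """Raised when an input file does not match its expected format."""


def _find_column(df: pd.DataFrame, candidates: List[str]) -> Optional[str]:
    lower = {str(c).strip().lower(): c for c in df.columns}
    for cand in candidates:
        if cand.lower() in lower:
            return lower[cand.lower()]
    # prefix match handles WGCNA's "nodeAttr[nodesPresent, ]"
    for cand in candidates:
        for key, orig in lower.items():
            if key.startswith(cand.lower()):
                return orig
    return None


def read_wgcna_tables(
    node_path,
    edge_path,
    condition_name: str = "",
    weight_floor: Optional[float] = None,
) -> CoexpressionNetwork:
    """Load a WGCNA-exported node table + edge table into a network.

    Duplicate unordered pairs keep the maximum weight; self-pairs are
    dropped (and counted in the log); edges below ``weight_floor`` are
    excluded. Genes that appear in the edge table but not in the node
    table are retained with the ``grey`` (unassigned) module and a warning.
    """
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    if nodes.shape[1] < 2:
        raise FormatError(
            f"node table {node_path}: need gene-id and module columns, "
            f"found {nodes.shape[1]} column(s)"
        )
    id_col = _find_column(nodes, ["nodeName", "gene", "geneid", "gene_id", "id"])
    mod_col = _find_column(
        nodes, ["nodeAttr", "module", "moduleColor", "module_color", "color"]
    )
    if id_col is None or mod_col is None:
        cols = list(nodes.columns)
        id_col = id_col or cols[0]
        if mod_col is None:
            mod_col = cols[2] if len(cols) >= 3 else cols[1]
        logger.warning(
            "node table %s: unrecognized header %s; using positional columns "
            "(%s=gene id, %s=module)",
            node_path,
            cols,
            id_col,
            mod_col,
        )
    assignment = {
        normalize_gene_id(g): normalize_module_label(m)
        for g, m in zip(nodes[id_col], nodes[mod_col])
        if pd.notna(g)
    }
    partition = ModulePartition(assignment, condition_name=condition_name)

    edges_df = pd.read_csv(edge_path, sep="\t")
    edge_dict: Dict[Tuple[str, str], float] = {}
    if edges_df.shape[0] > 0 or edges_df.shape[1] > 0:
        from_col = _find_column(edges_df, ["fromNode", "from", "source", "node1"])
        to_col = _find_column(edges_df, ["toNode", "to", "target", "node2"])
        w_col = _find_column(edges_df, ["weight", "adjacency"])
        if from_col is None or to_col is None or w_col is None:
            cols = list(edges_df.columns)
            if len(cols) < 3:
                raise FormatError(
                    f"edge table {edge_path}: need from/to/weight columns, "
                    f"found {cols}"
                )
            from_col, to_col, w_col = cols[0], cols[1], cols[2]
            logger.warning(
                "edge table %s: unrecognized header; using positional columns "
                "(1=from, 2=to, 3=weight)",
                edge_path,
            )
        n_self = 0
        unknown = set()
        for row_i, (a, b, w) in enumerate(
            zip(edges_df[from_col], edges_df[to_col], edges_df[w_col]), start=2
        ):
            a, b = normalize_gene_id(a), normalize_gene_id(b)
            try:
                w = float(w)
            except (TypeError, ValueError):
                raise FormatError(
                    f"edge table {edge_path}: non-numeric weight {w!r} at line {row_i}"
                ) from None
            if a == b:
                n_self += 1
                continue
            if weight_floor is not None and w < weight_floor:
                continue
            for g in (a, b):
                if g not in partition.assignment:
                    unknown.add(g)
            key = undirected_key(a, b)
            if key not in edge_dict or w > edge_dict[key]:
                edge_dict[key] = w
        if n_self:
            logger.info("edge table %s: dropped %d self-pairs", edge_path, n_self)
        if unknown:
            logger.warning(
                "edge table %s: %d gene(s) missing from node table; "
                "assigned module '%s'",
                edge_path,
                len(unknown),
                UNASSIGNED_MODULE,
            )
            for g in sorted(unknown):
                partition.assignment[g] = UNASSIGNED_MODULE
    return CoexpressionNetwork(edge_dict, partition, condition_name=condition_name)


def read_grn(
    path, condition_name: str = "", importance_floor: Optional[float] = None
) -> RegulatoryNetwork:
    """Load a GRNBoost2-style TSV (TF, target, importance).

    Ordered-pair duplicates keep the maximum importance; TF==target rows are
    dropped and counted; rows below ``importance_floor`` are excluded.
    """
    df = pd.read_csv(path, sep="\t")
    tf_col = _find_column(df, ["TF", "tf", "regulator"])
    tg_col = _find_column(df, ["target", "gene"])
    imp_col = _find_column(df, ["importance", "weight", "score"])
    if tf_col is None or tg_col is None or imp_col is None:
        raise FormatError(
            f"GRN file {path}: expected columns TF/target/importance, "
            f"found {list(df.columns)}"
        )
    edges: Dict[Tuple[str, str], float] = {}
    n_self = 0
    for row_i, (tf, tg, imp) in enumerate(
        zip(df[tf_col], df[tg_col], df[imp_col]), start=2
    ):
        tf, tg = normalize_gene_id(tf), normalize_gene_id(tg)
        try:
            imp = float(imp)
        except (TypeError, ValueError):
            raise FormatError(
                f"GRN file {path}: non-numeric importance {imp!r} at line {row_i}"
            ) from None
        if tf == tg:
            n_self += 1
            continue
        if importance_floor is not None and imp < importance_floor:
            continue
        key = (tf, tg)
        if key not in edges or imp > edges[key]:
            edges[key] = imp
    if n_self:
        logger.info("GRN file %s: dropped %d self-loops", path, n_self)
    return RegulatoryNetwork(edges, condition_name=condition_name)


def read_tf_list(path, id_column: str = "Protein ID") -> TFList:
    """Load a TF list CSV, deduplicating case-normalized ids."""
    df = pd.read_csv(path)
    col = _find_column(df, [id_column])
    if col is None:
        raise FormatError(
            f"TF list {path}: column {id_column!r} not found in {list(df.columns)}"
        )
    ids = {normalize_gene_id(g) for g in df[col].dropna()}
    if not ids:
        raise FormatError(f"TF list {path}: empty TF list")
    return TFList(ids)


_CURATED_HEADER_TOKENS = {"tf", "source", "regulator", "from", "tf_id"}


def read_curated_tf_targets(path) -> CuratedTFNetwork:
    """Load a curated TF->target pair list (TSV, optional source column)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(
            f"curated network {path}: need at least two columns (tf, target)"
        )
    if str(df.iloc[0, 0]).strip().lower() in _CURATED_HEADER_TOKENS:
        df = df.iloc[1:]
    if df.shape[0] == 0:
        raise FormatError(f"curated network {path}: no TF-target pairs")
    pairs = set()
    sources = set()
    for row in df.itertuples(index=False):
        tf, tg = normalize_gene_id(row[0]), normalize_gene_id(row[1])
        if tf == tg:
            logger.warning("curated network %s: dropped self-pair %s", path, tf)
            continue
        pairs.add((tf, tg))
        if len(row) >= 3 and pd.notna(row[2]):
            sources.add(str(row[2]))
    return CuratedTFNetwork(pairs, sources=sorted(sources))


def write_gmt(partition: ModulePartition, description: str, path) -> None:
    """Write the partition as a GMT file: one module set per line.

    Each row is ``label<TAB>description<TAB>gene1<TAB>gene2...``. Module
    order and within-module gene order are sorted for determinism.
    """
    if len(partition) == 0:
        raise ValueError("cannot write GMT from an empty partition")
    modules = partition.modules()
    with open(path, "w") as fh:
        for label in sorted(modules):
            genes = sorted(modules[label])
            fh.write("\t".join([label, description, *genes]) + "\n")
    logger.info("wrote %s: %d modules, %d genes", path, len(modules), len(partition))


def read_gmt(path, condition_name: str = "") -> ModulePartition:
    """Read a GMT file back into a partition (last assignment wins)."""
    assignment: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT {path}: row has {len(fields)} fields, need >= 3"
                )
            label = normalize_module_label(fields[0])
            for g in fields[2:]:
                if g:
                    assignment[normalize_gene_id(g)] = label
    return ModulePartition(assignment, condition_name=condition_name)


def cern_to_graph(cern: CERN) -> nx.DiGraph:
    """Materialize a CERN as a networkx DiGraph with full annotations."""
    g = nx.DiGraph(condition=cern.condition_name)
    for node, attrs in cern.node_annotations.items():
        g.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
    for (tf, tg), attrs in cern.edges.items():
        g.add_edge(tf, tg, **attrs)
    return g


def graph_to_cern(g: nx.DiGraph, condition_name: str = "") -> CERN:
    edges = {
        (u, v): {k: val for k, val in d.items()} for u, v, d in g.edges(data=True)
    }
    annotations = {n: dict(d) for n, d in g.nodes(data=True)}
    return CERN(
        edges,
        annotations,
        condition_name=condition_name or g.graph.get("condition", ""),
    )


def write_graphml(cern: CERN, path) -> None:
    """Export a CERN to GraphML (directed, fully attributed)."""
    nx.write_graphml(cern_to_graph(cern), path)
    logger.info(
        "wrote %s: %d nodes, %d edges", path, len(cern.nodes), cern.n_edges
    )


def read_graphml(path, condition_name: str = "") -> CERN:
    """Load a CERN back from GraphML."""
    g = nx.read_graphml(path)
    if not g.is_directed():
        g = g.to_directed()
    return graph_to_cern(g, condition_name=condition_name)
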