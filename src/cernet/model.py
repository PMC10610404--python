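"""Core domain types for co-expression / regulatory network integration.

The objects here are deliberately thin, validated containers:

* :class:`ModulePartition` — gene -> module-colour assignment for one
  condition (the WGCNA convention: modules are named by colours, ``grey``
  holds unassigned genes).
* :class:`CoexpressionNetwork` — undirected, weighted gene–gene edges plus
  a partition.
* :class:`RegulatoryNetwork` — directed TF->target edges weighted by an
  inference importance score.
* :class:`CuratedTFNetwork` / :class:`TFList` — auxiliary evidence used to
  denoise inferred regulatory edges.
* :class:`CERN` — the co-expressed regulatory network: directed TF->target
  edges whose gene pair is also co-expressed; carries both the regulatory
  importance and the co-expression weight.

All gene identifiers are canonicalized to upper case on entry so that
identifiers from mixed sources (arrays, curated lists, inference output)
compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Set, Tuple

logger = logging.getLogger("cernet")

#: WGCNA's label for genes not assigned to any co-expression module.
UNASSIGNED_MODULE = "grey"


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def normalize_gene_id(raw: str) -> str:
    """Canonicalize a gene identifier: strip whitespace, upper-case.

    Raises :class:`ValidationError` for empty ids or ids containing
    internal whitespace.
    """
    if raw is None:
        raise ValidationError("gene id is missing")
    gid = str(raw).strip().upper()
    if not gid:
        raise ValidationError("gene id is empty")
    if any(c.isspace() for c in gid):
        raise ValidationError(f"gene id contains whitespace: {raw!r}")
    return gid


def normalize_module_label(raw: str) -> str:
    label = str(raw).strip().lower()
    if not label:
        raise ValidationError("module label is empty")
    return label


def undirected_key(a: str, b: str) -> Tuple[str, str]:
    """Canonical (sorted) key for an unordered gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ModulePartition:
    """Mapping gene -> module label for one condition."""

    assignment: Dict[str, str]
    condition_name: str = ""

    def __post_init__(self) -> None:
        clean: Dict[str, str] = {}
        for gene, label in self.assignment.items():
            clean[normalize_gene_id(gene)] = normalize_module_label(label)
        self.assignment = clean

    def __len__(self) -> int:
        return len(self.assignment)

    @property
    def genes(self) -> Set[str]:
        return set(self.assignment)

    def modules(self, include_unassigned: bool = True) -> Dict[str, Set[str]]:
        """Module label -> member gene set."""
        out: Dict[str, Set[str]] = {}
        for gene, label in self.assignment.items():
            if not include_unassigned and label == UNASSIGNED_MODULE:
                continue
            out.setdefault(label, set()).add(gene)
        return out

    def module_sizes(self, include_unassigned: bool = True) -> Dict[str, int]:
        return {m: len(g) for m, g in self.modules(include_unassigned).items()}

    def label_of(self, gene: str) -> str:
        return self.assignment.get(gene, UNASSIGNED_MODULE)


@dataclass
class CoexpressionNetwork:
    """Undirected weighted gene–gene network with a module partition.

    ``edges`` maps the canonical sorted gene pair to an adjacency weight in
    [0, 1]. Self-pairs are rejected; nodes may exist only through the
    partition (isolated genes).
    """

    edges: Dict[Tuple[str, str], float]
    partition: ModulePartition
    condition_name: str = ""

    def __post_init__(self) -> None:
        clean: Dict[Tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            a, b = normalize_gene_id(a), normalize_gene_id(b)
            if a == b:
                raise ValidationError(f"self-pair {a!r} in co-expression edges")
            w = float(w)
            if not (0.0 <= w <= 1.0):
                raise ValidationError(
                    f"adjacency weight {w} outside [0, 1] for pair ({a}, {b})"
                )
            key = undirected_key(a, b)
            # duplicate unordered pairs keep the strongest evidence
            if key not in clean or w > clean[key]:
                clean[key] = w
        self.edges = clean

    @property
    def nodes(self) -> Set[str]:
        ns: Set[str] = set()
        for a, b in self.edges:
            ns.add(a)
            ns.add(b)
        return ns | self.partition.genes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_pair(self, a: str, b: str) -> bool:
        return undirected_key(a, b) in self.edges

    def weight(self, a: str, b: str) -> float:
        return self.edges[undirected_key(a, b)]


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target network weighted by an importance score."""

    edges: Dict[Tuple[str, str], float]
    condition_name: str = ""

    def __post_init__(self) -> None:
        clean: Dict[Tuple[str, str], float] = {}
        for (tf, tg), imp in self.edges.items():
            tf, tg = normalize_gene_id(tf), normalize_gene_id(tg)
            if tf == tg:
                raise ValidationError(f"self-loop {tf!r} in regulatory edges")
            imp = float(imp)
            if imp < 0:
                raise ValidationError(
                    f"negative importance {imp} for edge ({tf}, {tg})"
                )
            key = (tf, tg)
            if key not in clean or imp > clean[key]:
                clean[key] = imp
        self.edges = clean

    @property
    def nodes(self) -> Set[str]:
        ns: Set[str] = set()
        for tf, tg in self.edges:
            ns.add(tf)
            ns.add(tg)
        return ns

    @property
    def tfs(self) -> Set[str]:
        return {tf for tf, _ in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class CuratedTFNetwork:
    """Experimentally supported TF -> target pairs used for GRN denoising."""

    pairs: Set[Tuple[str, str]]
    sources: list = field(default_factory=list)

    def __post_init__(self) -> None:
        clean: Set[Tuple[str, str]] = set()
        dropped = 0
        for tf, tg in self.pairs:
            tf, tg = normalize_gene_id(tf), normalize_gene_id(tg)
            if tf == tg:
                dropped += 1
                continue
            clean.add((tf, tg))
        if dropped:
            logger.warning("dropped %d self-pairs from curated TF-target set", dropped)
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass
class TFList:
    """Set of transcription-factor gene ids."""

    ids: Set[str]

    def __post_init__(self) -> None:
        self.ids = {normalize_gene_id(g) for g in self.ids}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ids


@dataclass
class CERN:
    """Co-expressed regulatory network.

    ``edges`` maps the ordered (tf, target) pair to a dict with keys
    ``importance`` (from the regulatory network) and ``coexp_weight``
    (from the co-expression network). ``node_annotations`` maps each node
    to at least ``module`` and ``is_tf``; centrality scores are added in
    place by :func:`cernet.integration.network_centrality`.
    """

    edges: Dict[Tuple[str, str], Dict[str, float]]
    node_annotations: Dict[str, Dict[str, object]]
    condition_name: str = ""

    @property
    def nodes(self) -> Set[str]:
        return set(self.node_annotations)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> Set[Tuple[str, str]]:
        return set(self.edges)


def partition_from_pairs(
    pairs: Iterable[Tuple[str, str]], condition_name: str = ""
) -> ModulePartition:
    """Build a partition from (gene, module) pairs; later entries win."""
    return ModulePartition(dict(pairs), condition_name=condition_name)


def background_union(
    net_a: CoexpressionNetwork, net_b: CoexpressionNetwork
) -> Set[str]:
    """Default enrichment universe: union of both networks' node sets."""
    return net_a.nodes | net_b.nodes
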