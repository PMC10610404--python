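"""Synthetic two-condition fixtures with known ground truth.

The generator emulates, at desk scale, the data a real run consumes:

* block-correlated expression — genes of one module share a latent factor,
  ``x = sqrt(rho) * f_m + sqrt(1 - rho) * eps``, so any two genes of the
  same module have population correlation ``rho``; unassigned genes are
  pure noise;
* two module partitions with a controlled cross-condition Jaccard overlap
  between matched module pairs (the planted enrichment signal);
* a regulatory network whose true TF->target edges connect designated
  module-member TFs to their module mates (importance = |r|), salted with
  decoy edges that are absent from the curated truth set — so curated
  filtering has a known right answer.

The default configuration is the study condition exercised throughout the
test-suite: five modules of 60 genes, within-module correlation 0.85,
30 samples per condition, matched-module Jaccard 0.6, decoy fraction 0.5.

Everything is deterministic under a fixed seed. Gene ids follow the AGI
locus pattern (``AT1G00010`` ...) so fixtures exercise the same parsers
as real Arabidopsis data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import (
    CoexpressionNetwork,
    CuratedTFNetwork,
    ModulePartition,
    RegulatoryNetwork,
    TFList,
    UNASSIGNED_MODULE,
    undirected_key,
)

logger = logging.getLogger("cernet")

#: Module colours assigned to planted modules, in WGCNA canonical order.
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon",
)


@dataclass
class SimulationConfig:
    """Parameters of the two-condition synthetic study."""

    n_genes: int = 400
    n_samples_per_condition: int = 30
    module_sizes: Tuple[int, ...] = (60, 60, 60, 60, 60)
    within_module_correlation: float = 0.85
    cross_condition_module_jaccard: float = 0.6
    tf_per_module: int = 3
    decoy_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    condition_names: Tuple[str, str] = ("condA", "condB")

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_condition <= 0:
            raise ValueError("n_genes and n_samples_per_condition must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not (0.0 < self.within_module_correlation < 1.0):
            raise ValueError("within_module_correlation must be in (0, 1)")
        if not (0.0 <= self.cross_condition_module_jaccard <= 1.0):
            raise ValueError("cross_condition_module_jaccard must be in [0, 1]")
        if self.tf_per_module < 1:
            raise ValueError("tf_per_module must be >= 1")
        if not (0.0 <= self.decoy_fraction):
            raise ValueError("decoy_fraction must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.module_sizes) > len(_MODULE_COLORS):
            raise ValueError(
                f"at most {len(_MODULE_COLORS)} planted modules supported"
            )

    def gene_ids(self) -> List[str]:
        """AGI-style gene identifiers AT<chr>G<5 digits>."""
        return [
            f"AT{(i % 5) + 1}G{(i // 5 + 1) * 10:05d}" for i in range(self.n_genes)
        ]


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def planted_partitions(
    config: SimulationConfig,
) -> Tuple[ModulePartition, ModulePartition, Dict[str, str]]:
    """Two partitions whose matched modules overlap at the target Jaccard.

    Condition-A modules tile the head of the gene list; each condition-B
    module keeps a fraction of its matched A module and refills from genes
    unassigned in A, so the realized Jaccard of a matched pair is
    ``round(2*j*s/(1+j)) / (2*s - round(2*j*s/(1+j)))`` — within rounding
    of the requested value. Returns (partition_a, partition_b, matching)
    where matching maps A-module colour -> B-module colour.
    """
    genes = config.gene_ids()
    j = config.cross_condition_module_jaccard
    rng = _rng(config, 1)

    assign_a: Dict[str, str] = {g: UNASSIGNED_MODULE for g in genes}
    assign_b: Dict[str, str] = {g: UNASSIGNED_MODULE for g in genes}
    cursor = 0
    modules_a: List[Tuple[str, List[str]]] = []
    for color, size in zip(_MODULE_COLORS, config.module_sizes):
        members = genes[cursor : cursor + size]
        cursor += size
        for g in members:
            assign_a[g] = color
        modules_a.append((color, members))

    free_pool = [g for g in genes[cursor:]]  # unassigned in A
    rng.shuffle(free_pool)
    matching: Dict[str, str] = {}
    pool_idx = 0
    for color, members in modules_a:
        size = len(members)
        keep = int(round(2 * j * size / (1 + j)))  # |A∩B| for equal sizes
        keep = min(keep, size)
        refill = size - keep
        if pool_idx + refill > len(free_pool):
            raise ValueError(
                "infeasible Jaccard: not enough unassigned genes to refill "
                f"module {color} (need {refill}, have {len(free_pool) - pool_idx})"
            )
        kept = list(rng.choice(members, size=keep, replace=False))
        fresh = free_pool[pool_idx : pool_idx + refill]
        pool_idx += refill
        for g in kept + fresh:
            assign_b[g] = color
        matching[color] = color
    part_a = ModulePartition(assign_a, condition_name=config.condition_names[0])
    part_b = ModulePartition(assign_b, condition_name=config.condition_names[1])
    return part_a, part_b, matching


def simulate_expression(
    config: SimulationConfig,
    partitions: Optional[Tuple[ModulePartition, ModulePartition]] = None,
) -> Dict[str, pd.DataFrame]:
    """Gene x sample expression matrices for both conditions.

    Within a condition, genes of module m are ``sqrt(rho)*f_m +
    sqrt(1-rho)*eps`` (both standard normal, scaled by ``noise_sd``), so
    the population correlation of two same-module genes is exactly rho;
    unassigned genes are independent noise.
    """
    if partitions is None:
        part_a, part_b, _ = planted_partitions(config)
    else:
        part_a, part_b = partitions
    rho = config.within_module_correlation
    n_samp = config.n_samples_per_condition
    out: Dict[str, pd.DataFrame] = {}
    for cond_i, (cond, part) in enumerate(
        zip(config.condition_names, (part_a, part_b))
    ):
        rng = _rng(config, 100 + cond_i)
        genes = config.gene_ids()
        modules = part.modules(include_unassigned=False)
        factors = {m: rng.standard_normal(n_samp) for m in sorted(modules)}
        x = np.empty((len(genes), n_samp))
        for gi, g in enumerate(genes):
            label = part.label_of(g)
            eps = rng.standard_normal(n_samp)
            if label != UNASSIGNED_MODULE:
                sig = np.sqrt(rho) * factors[label] + np.sqrt(1 - rho) * eps
            else:
                sig = eps
            x[gi] = config.noise_sd * sig
        out[cond] = pd.DataFrame(
            x, index=genes, columns=[f"{cond}_s{i+1}" for i in range(n_samp)]
        )
    return out


def infer_coexpression(
    expr: pd.DataFrame,
    partition: ModulePartition,
    r_threshold: float = 0.7,
    condition_name: str = "",
) -> CoexpressionNetwork:
    """Correlation-threshold co-expression network (WGCNA stand-in).

    Edges connect gene pairs with |Pearson r| >= threshold; the edge
    weight is |r|. Zero-variance genes are excluded with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "excluded %d zero-variance gene(s) from co-expression",
            int((~keep).sum()),
        )
    genes = [g for g, k in zip(expr.index, keep) if k]
    edges: Dict[Tuple[str, str], float] = {}
    if len(genes) >= 2:
        r = np.corrcoef(values[keep])
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        ii, jj = np.nonzero(np.triu(absr >= r_threshold, k=1))
        edges = {
            undirected_key(genes[i], genes[j]): min(float(absr[i, j]), 1.0)
            for i, j in zip(ii, jj)
        }
    name = condition_name or partition.condition_name
    return CoexpressionNetwork(edges, partition, condition_name=name)


def _planted_true_edges(
    expr: pd.DataFrame, partition: ModulePartition, config: SimulationConfig
) -> Dict[Tuple[str, str], float]:
    """TF -> same-module-member edges, importance = empirical |r|."""
    modules = partition.modules(include_unassigned=False)
    gene_idx = {g: i for i, g in enumerate(expr.index)}
    values = expr.to_numpy(dtype=float)
    true_edges: Dict[Tuple[str, str], float] = {}
    for label in sorted(modules):
        members = sorted(modules[label])
        tfs = members[: config.tf_per_module]
        for tf in tfs:
            for target in members:
                if target == tf:
                    continue
                r = np.corrcoef(values[gene_idx[tf]], values[gene_idx[target]])[0, 1]
                true_edges[(tf, target)] = abs(float(r))
    return true_edges


def simulate_grn(
    expr: pd.DataFrame,
    partition: ModulePartition,
    config: SimulationConfig,
    salt: int = 0,
    forbidden_decoys: Optional[Set[Tuple[str, str]]] = None,
) -> Tuple[RegulatoryNetwork, CuratedTFNetwork, TFList]:
    """A GRN with planted truth plus decoys, and the matching curated set.

    The first ``tf_per_module`` genes of each module act as TFs; every
    TF -> same-module-member pair is a true edge with importance equal to
    the empirical |r|. Decoy edges (``decoy_fraction`` x the true count)
    are random ordered pairs outside the truth set with low importance;
    the curated network contains exactly the true edges, so curated
    filtering removes exactly the decoys. ``forbidden_decoys`` lets a
    multi-condition study keep decoys out of the *combined* curated set
    (decoys must not collide with another condition's true edges).
    """
    rng = _rng(config, 200 + salt)
    genes = list(expr.index)
    true_edges = _planted_true_edges(expr, partition, config)
    forbidden = set(true_edges)
    if forbidden_decoys:
        forbidden |= forbidden_decoys

    n_decoys = int(round(config.decoy_fraction * len(true_edges)))
    decoys: Dict[Tuple[str, str], float] = {}
    max_tries = 50 * max(n_decoys, 1)
    tries = 0
    while len(decoys) < n_decoys and tries < max_tries:
        tries += 1
        tf, tg = rng.choice(genes, size=2, replace=False)
        pair = (str(tf), str(tg))
        if pair in forbidden or pair in decoys:
            continue
        decoys[pair] = float(rng.uniform(0.01, 0.3))
    if len(decoys) < n_decoys:
        logger.warning("only %d of %d decoy edges placed", len(decoys), n_decoys)

    grn = RegulatoryNetwork(
        {**true_edges, **decoys}, condition_name=partition.condition_name
    )
    curated = CuratedTFNetwork(set(true_edges), sources=["synthetic_truth"])
    all_tfs = {tf for tf, _ in true_edges}
    return grn, curated, TFList(all_tfs)


def random_partition(
    genes: Sequence[str],
    rng: np.random.Generator,
    size_range: Tuple[int, int] = (100, 400),
    min_size: int = 50,
    condition_name: str = "",
) -> ModulePartition:
    """Uniform random module partition (null model, no planted structure).

    Genes are shuffled and cut into modules with sizes drawn uniformly
    from ``size_range``; a final remainder smaller than ``min_size`` is
    merged into the last module. Every gene is assigned, so each module
    is marginally a uniform random subset of the universe.
    """
    order = list(genes)
    rng.shuffle(order)
    sizes: List[int] = []
    remaining = len(order)
    while remaining >= size_range[0]:
        s = int(rng.integers(size_range[0], size_range[1] + 1))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    if remaining:
        if remaining >= min_size or not sizes:
            sizes.append(remaining)
        else:
            sizes[-1] += remaining
    assignment: Dict[str, str] = {}
    cursor = 0
    for mi, s in enumerate(sizes):
        label = f"m{mi:02d}"
        for g in order[cursor : cursor + s]:
            assignment[g] = label
        cursor += s
    return ModulePartition(assignment, condition_name=condition_name)


@dataclass
class SyntheticStudy:
    """Everything one two-condition run needs, with ground truth attached."""

    config: SimulationConfig
    expression: Dict[str, pd.DataFrame]
    partitions: Tuple[ModulePartition, ModulePartition]
    matching: Dict[str, str]
    networks: Tuple[CoexpressionNetwork, CoexpressionNetwork]
    grns: Tuple[RegulatoryNetwork, RegulatoryNetwork]
    curated: CuratedTFNetwork
    tf_list: TFList
    true_edges: Tuple[Set[Tuple[str, str]], Set[Tuple[str, str]]]


def generate_study(
    config: Optional[SimulationConfig] = None, r_threshold: float = 0.7
) -> SyntheticStudy:
    """Run the full generator: partitions -> expression -> networks -> GRNs."""
    config = config or SimulationConfig()
    part_a, part_b, matching = planted_partitions(config)
    expr = simulate_expression(config, (part_a, part_b))
    cond_a, cond_b = config.condition_names
    net_a = infer_coexpression(expr[cond_a], part_a, r_threshold, cond_a)
    net_b = infer_coexpression(expr[cond_b], part_b, r_threshold, cond_b)
    true_a = set(_planted_true_edges(expr[cond_a], part_a, config))
    true_b = set(_planted_true_edges(expr[cond_b], part_b, config))
    grn_a, curated_a, tfs_a = simulate_grn(
        expr[cond_a], part_a, config, salt=0, forbidden_decoys=true_b
    )
    grn_b, curated_b, tfs_b = simulate_grn(
        expr[cond_b], part_b, config, salt=1, forbidden_decoys=true_a
    )
    curated = CuratedTFNetwork(
        curated_a.pairs | curated_b.pairs, sources=["synthetic_truth"]
    )
    tf_list = TFList(tfs_a.ids | tfs_b.ids)
    return SyntheticStudy(
        config=config,
        expression=expr,
        partitions=(part_a, part_b),
        matching=matching,
        networks=(net_a, net_b),
        grns=(grn_a, grn_b),
        curated=curated,
        tf_list=tf_list,
        true_edges=(set(curated_a.pairs), set(curated_b.pairs)),
    )


def write_fixture_dir(study: SyntheticStudy, outdir) -> Dict[str, Dict[str, str]]:
    """Write the study in the exact file formats the readers consume.

    Per condition: WGCNA-style node/edge TSVs, a GRN TSV and an expression
    CSV; shared: curated TF->target TSV and TF-list CSV. Returns the path
    map (condition -> role -> path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Dict[str, str]] = {}
    for cond, part, net, grn in zip(
        study.config.condition_names,
        study.partitions,
        study.networks,
        study.grns,
    ):
        node_path = outdir / f"Nodes_{cond}.txt"
        edge_path = outdir / f"Edges_{cond}.txt"
        grn_path = outdir / f"GRN_{cond}.tsv"
        expr_path = outdir / f"Expr_{cond}.csv"
        pd.DataFrame(
            {
                "nodeName": sorted(part.assignment),
                "altName": sorted(part.assignment),
                "nodeAttr[nodesPresent, ]": [
                    part.assignment[g] for g in sorted(part.assignment)
                ],
            }
        ).to_csv(node_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"fromNode": a, "toNode": b, "weight": w}
                for (a, b), w in sorted(net.edges.items())
            ],
            columns=["fromNode", "toNode", "weight"],
        ).to_csv(edge_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"TF": tf, "target": tg, "importance": imp}
                for (tf, tg), imp in sorted(grn.edges.items())
            ],
            columns=["TF", "target", "importance"],
        ).to_csv(grn_path, sep="\t", index=False)
        study.expression[cond].to_csv(expr_path)
        paths[cond] = {
            "nodes": str(node_path),
            "edges": str(edge_path),
            "grn": str(grn_path),
            "expression": str(expr_path),
        }
    curated_path = outdir / "curated_tf_targets.tsv"
    with open(curated_path, "w") as fh:
        fh.write("tf\ttarget\tsource\n")
        for tf, tg in sorted(study.curated.pairs):
            fh.write(f"{tf}\t{tg}\tsynthetic_truth\n")
    tf_path = outdir / "tf_list.csv"
    pd.DataFrame({"Protein ID": sorted(study.tf_list.ids)}).to_csv(
        tf_path, index=False
    )
    paths["shared"] = {"curated": str(curated_path), "tf_list": str(tf_path)}
    return paths
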