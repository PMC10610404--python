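"""Two-condition comparison pipeline: load -> GMT -> enrichment ->
filter -> merge -> centrality -> export -> overlap, with a run manifest.

The run is configured by a single YAML file (see :class:`RunConfig`);
every stage logs its counts and records them in ``manifest.json`` so a run
can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import __version__
from .enrichment import (
    Background,
    DEFAULT_TIERS,
    enrichment_dotplot,
    module_enrichment,
)
from .integration import (
    centrality_frame,
    combined_cern,
    filter_grn,
    merge_reg_coexp,
    network_centrality,
    network_overlap,
)
from .io import (
    read_curated_tf_targets,
    read_grn,
    read_tf_list,
    read_wgcna_tables,
    write_gmt,
    write_graphml,
)
from .model import normalize_gene_id

logger = logging.getLogger("cernet")


@dataclass
class ConditionFiles:
    name: str
    nodes: str
    edges: str
    grn: str


@dataclass
class RunConfig:
    """Validated configuration of one comparison run."""

    condition_a: ConditionFiles
    condition_b: ConditionFiles
    output_dir: str = "cernet_out"
    curated: Optional[str] = None
    tf_list: Optional[str] = None
    tf_list_column: str = "Protein ID"
    background: Optional[str] = None
    filter_enabled: bool = True
    keep_grey: bool = False
    alpha_tiers: tuple = DEFAULT_TIERS
    weight_floor: Optional[float] = None
    importance_floor: Optional[float] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conds = raw.get("conditions")
        if not conds or len(conds) != 2:
            raise ValueError("config must define exactly two conditions")
        parsed = [
            ConditionFiles(
                name=str(c["name"]),
                nodes=str(c["nodes"]),
                edges=str(c["edges"]),
                grn=str(c["grn"]),
            )
            for c in conds
        ]
        cfg = cls(
            condition_a=parsed[0],
            condition_b=parsed[1],
            output_dir=str(raw.get("output_dir", "cernet_out")),
            curated=raw.get("curated"),
            tf_list=raw.get("tf_list"),
            tf_list_column=raw.get("tf_list_column", "Protein ID"),
            background=raw.get("background"),
            filter_enabled=bool(raw.get("filter", True)),
            keep_grey=bool(raw.get("keep_grey", False)),
            alpha_tiers=tuple(raw.get("alpha_tiers", DEFAULT_TIERS)),
            weight_floor=raw.get("weight_floor"),
            importance_floor=raw.get("importance_floor"),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = []
        for cond in (self.condition_a, self.condition_b):
            for role in ("nodes", "edges", "grn"):
                p = getattr(cond, role)
                if not Path(p).is_file():
                    missing.append(f"{cond.name}/{role}: {p}")
        for role in ("curated", "tf_list", "background"):
            p = getattr(self, role)
            if p is not None and not Path(p).is_file():
                missing.append(f"{role}: {p}")
        if missing:
            raise FileNotFoundError(
                "missing input file(s): " + "; ".join(missing)
            )


def _read_background(path) -> Background:
    genes = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0].split(",")[0]
            if token and not token.startswith("#"):
                genes.add(normalize_gene_id(token))
    return Background(genes, mode="explicit_list")


def run_compare(config: RunConfig) -> Dict:
    """Execute the full comparison; returns the manifest dict.

    Output bundle: two GMTs, enrichment TSV + dot plot, two centrality
    TSVs, per-condition CERN GraphMLs, a combined-network GraphML, the
    node-overlap TSV and ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "filter_enabled": config.filter_enabled,
            "keep_grey": config.keep_grey,
            "alpha_tiers": list(config.alpha_tiers),
            "weight_floor": config.weight_floor,
            "importance_floor": config.importance_floor,
        },
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    stage = "load"
    try:
        nets, grns = [], []
        for cond in (config.condition_a, config.condition_b):
            net = read_wgcna_tables(
                cond.nodes, cond.edges, cond.name, weight_floor=config.weight_floor
            )
            grn = read_grn(
                cond.grn, cond.name, importance_floor=config.importance_floor
            )
            nets.append(net)
            grns.append(grn)
            manifest["inputs"][cond.name] = {
                "nodes": cond.nodes,
                "edges": cond.edges,
                "grn": cond.grn,
            }
            manifest["stages"].setdefault(cond.name, {})
            manifest["stages"][cond.name]["coexp_nodes"] = len(net.nodes)
            manifest["stages"][cond.name]["coexp_edges"] = net.n_edges
            manifest["stages"][cond.name]["grn_edges_raw"] = grn.n_edges
        curated = (
            read_curated_tf_targets(config.curated) if config.curated else None
        )
        tf_list = (
            read_tf_list(config.tf_list, config.tf_list_column)
            if config.tf_list
            else None
        )
        background = (
            _read_background(config.background) if config.background else None
        )

        stage = "gmt"
        for net in nets:
            gmt_path = outdir / f"{net.condition_name}.gmt"
            write_gmt(net.partition, f"WGCNA{net.condition_name}", gmt_path)
            manifest["outputs"][f"gmt_{net.condition_name}"] = str(gmt_path)

        stage = "enrichment"
        table = module_enrichment(
            nets[0],
            nets[1],
            background=background,
            exclude_unassigned=not config.keep_grey,
            thresholds=config.alpha_tiers,
        )
        enr_tsv = outdir / "enrichment.tsv"
        enr_png = outdir / "enrichment_dotplot.png"
        enrichment_dotplot(table, enr_png, tsv_path=enr_tsv)
        manifest["outputs"]["enrichment_tsv"] = str(enr_tsv)
        manifest["outputs"]["enrichment_dotplot"] = str(enr_png)
        manifest["stages"]["enrichment_cells"] = len(table.cells)
        manifest["stages"]["enrichment_significant"] = sum(
            1 for c in table.cells if c.tier != "NE"
        )

        stage = "integrate"
        cerns = []
        for net, grn in zip(nets, grns):
            filtered = filter_grn(grn, curated, enabled=config.filter_enabled)
            cern = merge_reg_coexp(filtered, net, tf_list=tf_list)
            records = network_centrality(cern)
            cerns.append(cern)
            cname = net.condition_name
            manifest["stages"][cname]["grn_edges_filtered"] = filtered.n_edges
            manifest["stages"][cname]["cern_edges"] = cern.n_edges
            manifest["stages"][cname]["cern_nodes"] = len(cern.nodes)
            cent_path = outdir / f"centrality_{cname}.tsv"
            centrality_frame(records).to_csv(cent_path, sep="\t", index=False)
            gml_path = outdir / f"cern_{cname}.graphml"
            write_graphml(cern, gml_path)
            manifest["outputs"][f"centrality_{cname}"] = str(cent_path)
            manifest["outputs"][f"graphml_{cname}"] = str(gml_path)

        stage = "overlap"
        report = network_overlap(cerns[0], cerns[1])
        overlap_tsv = outdir / "node_overlap.tsv"
        report.to_frame().to_csv(overlap_tsv, sep="\t", index=False)
        combined = combined_cern(report, cerns[0], cerns[1])
        combined_path = outdir / "cern_combined.graphml"
        write_graphml(combined, combined_path)
        manifest["outputs"]["overlap_tsv"] = str(overlap_tsv)
        manifest["outputs"]["graphml_combined"] = str(combined_path)
        manifest["stages"]["overlap"] = {
            "shared": len(report.shared),
            "unique_a": len(report.unique_a),
            "unique_b": len(report.unique_b),
            "combined_nodes": report.n_combined_nodes,
            "combined_edges": len(report.combined_edges),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: outputs in %s", outdir)
    return manifest
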