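"""End-to-end pipeline: expression calls -> tissue networks -> CI-MDS ->
six-way classification (-> enrichment), with a machine-readable manifest.

The pipeline is a straight composition of the public module operations; it
performs no computation of its own beyond orchestration and file output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .classify import breadth_histogram, class_counts, classify_proteins, count_breadths
from .errors import ConfigurationError
from .graph_core import read_edge_list, write_edge_list
from .mds import solve_ci_mds
from .stats import fisher_enrichment, read_gmt
from .tissue_networks import build_all, call_expression, read_expression_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    global_edgelist: str
    expression_sources: list[dict] = field(default_factory=list)
    ell: int = 1
    backend: str = "highs"
    hk_min: int = 14
    ts_max: int = 3
    ts_strict: bool = True
    universe: str = "union"  # or "global"
    gene_sets: str | None = None
    output_dir: str = "cimds_out"
    seed: int = 0

    def validate(self) -> None:
        if not self.expression_sources:
            raise ConfigurationError("at least one expression source is required")
        for src in self.expression_sources:
            if "path" not in src:
                raise ConfigurationError(f"expression source missing 'path': {src}")
            if "threshold" not in src or src["threshold"] is None:
                raise ConfigurationError(
                    f"expression source {src.get('path')} has no threshold; "
                    "thresholds are mandatory per source")
        if not (self.hk_min > self.ts_max >= 1):
            raise ConfigurationError(
                f"need hk_min > ts_max >= 1, got {self.hk_min}, {self.ts_max}")
        if self.universe not in ("union", "global"):
            raise ConfigurationError(f"universe must be union|global, not {self.universe!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Outputs under ``config.output_dir``: per-tissue edge lists, per-tissue
    CI-MDS member lists with gamma and total CI, the classification table,
    breadth histograms, optional enrichment table, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "mds").mkdir(exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}}

    global_net = read_edge_list(config.global_edgelist)
    manifest["stages"]["global"] = {"n_nodes": global_net.number_of_nodes(),
                                    "n_edges": global_net.number_of_edges()}

    tables = [read_expression_table(s["path"], s.get("name", s["path"]),
                                    float(s["threshold"]))
              for s in config.expression_sources]
    calls = call_expression(tables)
    networks = build_all(global_net, calls)
    summary_lines = ["tissue\tn_nodes\tn_edges\tgamma\ttotal_ci"]
    mds_sets: dict[str, set[str]] = {}
    tissue_stats = {}
    for tissue in networks.tissues:
        net = networks.networks[tissue]
        write_edge_list(net, out / "networks" / f"{tissue}.tsv")
        result = solve_ci_mds(net, ell=config.ell, backend=config.backend)
        mds_sets[tissue] = set(result.members)
        (out / "mds" / f"{tissue}.members.txt").write_text(
            "".join(m + "\n" for m in sorted(result.members)))
        (out / "mds" / f"{tissue}.json").write_text(json.dumps(
            {"gamma": result.size, "total_ci": result.total_ci,
             "members": sorted(result.members), "backend": result.backend}, indent=1))
        tissue_stats[tissue] = {"n_nodes": net.number_of_nodes(),
                                "n_edges": net.number_of_edges(),
                                "gamma": result.size, "total_ci": result.total_ci}
        summary_lines.append(f"{tissue}\t{net.number_of_nodes()}\t"
                             f"{net.number_of_edges()}\t{result.size}\t{result.total_ci}")
        logger.info("tissue %s: gamma=%d total_ci=%d", tissue, result.size,
                    result.total_ci)
    (out / "summary.tsv").write_text("".join(l + "\n" for l in summary_lines))
    manifest["stages"]["tissues"] = tissue_stats
    manifest["stages"]["skipped_tissues"] = networks.skipped

    breadths = count_breadths(networks, mds_sets)
    records = classify_proteins(breadths, hk_min=config.hk_min,
                                ts_max=config.ts_max, ts_strict=config.ts_strict)
    with (out / "classification.tsv").open("w") as fh:
        fh.write("protein\tn_expressed\tn_mds\tlabel\n")
        for r in records:
            fh.write(f"{r.protein}\t{r.n_expressed}\t{r.n_mds}\t{r.label}\n")
    t = len(networks.tissues)
    hist_exp = breadth_histogram(breadths, "expressed", n_tissues=t)
    hist_mds = breadth_histogram(breadths, "mds", n_tissues=t)
    summary = {"class_counts": class_counts(records),
               "expressed_breadth": hist_exp, "mds_breadth": hist_mds}
    (out / "class_summary.json").write_text(json.dumps(summary, indent=1))
    manifest["stages"]["classification"] = summary["class_counts"]

    if config.gene_sets:
        universe = (set(breadths) if config.universe == "union"
                    else set(global_net.nodes()))
        gene_sets = read_gmt(config.gene_sets)
        class_members: dict[str, set[str]] = {}
        for r in records:
            class_members.setdefault(r.label, set()).add(r.protein)
        class_members["MDS"] = {r.protein for r in records if r.is_mds}
        lines = ["set\tclass\tin_class_in_set\tin_class_total\tpct\tp_value"]
        for set_name, members in gene_sets.items():
            for cls_name in ("MDS", "HK-MDS", "TS-MDS"):
                cls = class_members.get(cls_name, set())
                if not (cls & universe):
                    continue
                res = fisher_enrichment(cls, members, universe)
                lines.append(f"{set_name}\t{cls_name}\t{res.in_class_in_set}\t"
                             f"{res.in_class_total}\t{100 * res.fraction:.1f}\t"
                             f"{res.p_value:.3e}")
        (out / "enrichment.tsv").write_text("".join(l + "\n" for l in lines))
        manifest["stages"]["enrichment"] = {"n_sets": len(gene_sets)}

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
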