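"""End-to-end pipeline: counting -> calling -> condition classification ->
clustering/QC, driven by a structured config and emitting a machine-readable
report alongside the per-stage TSV outputs."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .allelic import (
    CrossDirection,
    aggregate_gene_counts,
    read_gene_counts,
    read_snp_counts,
    read_snp_table,
    write_gene_counts,
)
from .expression import ExpressionMatrix, kmeans_cluster, relative_to_reference
from .imprinting import CallConfig, ImprintingModel, classify_condition_specific
from .simulate import SimConfig, simulate_allelic_counts, write_fixtures

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineReport:
    """Machine-readable run record: tallies per stage, resulting set sizes,
    and enough config echo to re-run identically."""

    version: str
    seed: int | None
    config_echo: dict[str, Any]
    stage_counts: dict[str, int] = field(default_factory=dict)
    filter_tallies: dict[str, int] = field(default_factory=dict)
    set_sizes: dict[str, int] = field(default_factory=dict)
    partitions: dict[str, dict[str, int]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineConfigError(f"config {path!r} must be a mapping")
    return config


def _validate_inputs(config: Mapping[str, Any], base_dir: str) -> None:
    """Fail fast, before any computation, on missing input files."""
    if "simulate" in config:
        return
    conditions = config.get("conditions")
    if not conditions:
        raise PipelineConfigError("config needs either a 'simulate' block or 'conditions'")
    for cond, spec in conditions.items():
        for key in ("cross1", "cross2"):
            if key not in spec:
                raise PipelineConfigError(f"condition {cond!r} missing {key!r}")
            path = os.path.join(base_dir, spec[key])
            if not os.path.exists(path):
                raise PipelineConfigError(f"condition {cond!r}: input file {path!r} not found")


def _call_config(config: Mapping[str, Any]) -> CallConfig:
    overrides = dict(config.get("call", {}))
    if "expected_maternal_ratio" in overrides:
        overrides["expected_maternal_ratio"] = float(overrides["expected_maternal_ratio"])
    return CallConfig(**overrides)


def run_pipeline(config: Mapping[str, Any], out_dir: str,
                 base_dir: str = ".") -> PipelineReport:
    """Run all stages and write TSV/JSON outputs under ``out_dir``.

    The config names gene-count inputs per condition and cross (or a
    ``simulate`` block generating them); any stage error aborts with the
    stage name in the exception context.
    """
    _validate_inputs(config, base_dir)
    os.makedirs(out_dir, exist_ok=True)
    seed = config.get("seed")
    report = PipelineReport(version=__version__, seed=seed, config_echo=dict(config))
    call_config = _call_config(config)

    # --- stage: obtain per-condition gene counts -------------------------
    condition_counts: dict[str, tuple[list, list]] = {}
    if "simulate" in config:
        if seed is None:
            raise PipelineConfigError("a seed is mandatory when simulating")
        sim_spec = dict(config["simulate"])
        cond_names = sim_spec.pop("conditions", ["dormant", "non_dormant"])
        if "depth_range" in sim_spec:
            sim_spec["depth_range"] = tuple(sim_spec["depth_range"])
        for i, cond in enumerate(cond_names):
            sim = SimConfig(seed=int(seed) + i, **sim_spec)
            c1, c2, truth = simulate_allelic_counts(sim)
            condition_counts[cond] = (c1, c2)
            truth_path = os.path.join(out_dir, f"truth_{cond}.tsv")
            truth.to_frame().to_csv(truth_path, sep="\t", index=False)
            report.outputs[f"truth_{cond}"] = truth_path
            report.stage_counts[f"simulated_genes_{cond}"] = sim.n_genes
    else:
        for cond, spec in config["conditions"].items():
            c1 = read_gene_counts(os.path.join(base_dir, spec["cross1"]))
            c2 = read_gene_counts(os.path.join(base_dir, spec["cross2"]))
            condition_counts[cond] = (c1, c2)
            report.stage_counts[f"gene_counts_{cond}_cross1"] = len(c1)
            report.stage_counts[f"gene_counts_{cond}_cross2"] = len(c2)

    # --- stage: imprinting calls per condition ---------------------------
    results_by_condition = {}
    for cond, (c1, c2) in condition_counts.items():
        model = ImprintingModel(c1, c2, condition=cond)
        res = model.fit(call_config)
        results_by_condition[cond] = res
        counts = res.class_counts()
        report.set_sizes[f"megs_{cond}"] = counts["MEG"]
        report.set_sizes[f"pegs_{cond}"] = counts["PEG"]
        report.filter_tallies[f"low_read_genes_{cond}"] = counts["low_reads"]
        report.filter_tallies[f"single_cross_genes_{cond}"] = model.n_single_cross
        logger.info("condition %s: %d low-read genes filtered", cond, counts["low_reads"])
        logger.info("condition %s: %d genes in one cross only", cond, model.n_single_cross)

        calls_path = os.path.join(out_dir, f"calls_{cond}.tsv")
        res.to_frame().to_csv(calls_path, sep="\t", index=False)
        report.outputs[f"calls_{cond}"] = calls_path
        for cls, attr in (("megs", "megs"), ("pegs", "pegs")):
            path = os.path.join(out_dir, f"{cls}_{cond}.txt")
            with open(path, "w") as fh:
                fh.writelines(f"{g}\n" for g in sorted(getattr(res.sets, attr)))
            report.outputs[f"{cls}_{cond}"] = path

    # --- stage: condition-specific classification ------------------------
    cond_names = list(results_by_condition)
    if len(cond_names) == 2:
        first, second = cond_names
        partition = classify_condition_specific(
            results_by_condition[first].sets, results_by_condition[second].sets)
        for cls, part in partition.items():
            report.partitions[cls] = {
                f"{first}_specific": len(part.specific_first),
                "shared": len(part.shared),
                f"{second}_specific": len(part.specific_second),
            }

    # --- stage: expression clustering (optional) -------------------------
    if "expression" in config:
        expr_spec = config["expression"]
        matrix = ExpressionMatrix.from_tsv(
            os.path.join(base_dir, expr_spec["matrix"]),
            os.path.join(base_dir, expr_spec["metadata"]) if "metadata" in expr_spec else None,
        )
        reference = expr_spec.get("reference", "ColxCvi")
        rel = relative_to_reference(matrix, reference)
        report.filter_tallies["zero_reference_genes_dropped"] = (
            len(matrix.genes) - len(rel.genes))
        logger.info("%d genes dropped with zero reference expression",
                    len(matrix.genes) - len(rel.genes))
        cluster_seed = int(expr_spec.get("cluster_seed", seed if seed is not None else 17))
        clusters = kmeans_cluster(rel, k=int(expr_spec.get("k", 3)), seed=cluster_seed,
                                  restarts=int(expr_spec.get("restarts", 25)))
        cluster_path = os.path.join(out_dir, "clusters.tsv")
        pd.DataFrame(sorted(clusters.assignments.items()),
                     columns=["gene_id", "cluster"]).to_csv(cluster_path, sep="\t",
                                                            index=False)
        report.outputs["clusters"] = cluster_path
        report.stage_counts["clustered_genes"] = len(clusters.assignments)

    report_path = os.path.join(out_dir, "report.json")
    report.to_json(report_path)
    report.outputs["report"] = report_path
    return report


def count_stage(snp_table_path: str, snp_counts_path: str, cross_label: str,
                out_path: str) -> int:
    """Standalone counting stage: per-SNP counts -> per-gene oriented totals."""
    sites = read_snp_table(snp_table_path)
    counts = read_snp_counts(snp_counts_path, sites)
    cross = CrossDirection.from_label(cross_label)
    gene_counts = aggregate_gene_counts(counts, cross)
    write_gene_counts(gene_counts, out_path)
    return len(gene_counts)
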