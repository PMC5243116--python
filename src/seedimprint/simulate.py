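"""Synthetic reciprocal-cross data with known ground truth.

The allelic-count generator encodes the triploid-endosperm null: a
biallelically expressed gene samples maternal reads with probability 2/3.
A planted minority of MEGs (high maternal fraction) and PEGs (low maternal
fraction) carries the same truth label in both cross directions, matching
the parent-of-origin (rather than allele-of-origin) signature the caller is
designed to detect.  Depth varies per gene and per cross; optional
beta-binomial overdispersion loosens the pure binomial sampling.

The expression-panel generator emulates a genotype-ordered FPKM panel over
(Cvi, CvixCol, ColxCvi, Col) with planted cluster structure and, optionally,
a cold/control contrast.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allelic import (
    COL_X_CVI,
    CVI_X_COL,
    CrossDirection,
    GeneAllelicCount,
    SnpSite,
    write_gene_counts,
    write_snp_table,
)
from .expression import DORMANCY_ORDER, ExpressionMatrix


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the allelic-count simulation.

    The null maternal fraction is fixed at 2/3 (triploid endosperm dosage).
    MEGs are planted at maternal fraction 0.95 and PEGs at 0.15; depths are
    drawn uniformly per gene per cross from ``depth_range`` (inclusive).
    ``overdispersion`` is a beta-binomial concentration: 0 means pure
    binomial sampling, smaller positive values mean noisier fractions.
    """

    n_genes: int = 1000
    frac_meg: float = 0.0
    frac_peg: float = 0.0
    meg_maternal_fraction: float = 0.95
    peg_maternal_fraction: float = 0.15
    depth_range: tuple[int, int] = (20, 200)
    overdispersion: float = 0.0
    seed: int = 0

    #: triploid-endosperm null; two maternal genomes, one paternal
    null_maternal_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("frac_meg", "frac_peg", "meg_maternal_fraction",
                     "peg_maternal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_meg + self.frac_peg > 1.0:
            raise ValueError("frac_meg + frac_peg must not exceed 1")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must be a positive interval")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")


@dataclass(frozen=True)
class SimTruth:
    """Planted per-gene labels and parameters for recovery testing."""

    labels: Mapping[str, str]  # gene -> MEG | PEG | biallelic
    maternal_fractions: Mapping[str, float]
    depths: Mapping[str, tuple[int, int]]  # gene -> (depth cross1, depth cross2)

    def genes_with_label(self, label: str) -> frozenset[str]:
        return frozenset(g for g, l in self.labels.items() if l == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g, self.labels[g], self.maternal_fractions[g], *self.depths[g])
                for g in sorted(self.labels)
            ],
            columns=["gene_id", "label", "true_maternal_fraction",
                     "depth_cross1", "depth_cross2"],
        )


def _draw_maternal(rng: np.random.Generator, depth: int, theta: float,
                   overdispersion: float) -> int:
    if overdispersion > 0:
        theta = rng.beta(theta * overdispersion, (1.0 - theta) * overdispersion)
    return int(rng.binomial(depth, theta))


def simulate_allelic_counts(
    config: SimConfig,
) -> tuple[list[GeneAllelicCount], list[GeneAllelicCount], SimTruth]:
    """Draw per-gene counts for both cross directions plus the ground truth.

    Reproducible for a fixed seed: one generator seeded once drives label
    assignment, depths and counts in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"ATSIM{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    u = rng.random(config.n_genes)
    labels = np.where(
        u < config.frac_meg, "MEG",
        np.where(u < config.frac_meg + config.frac_peg, "PEG", "biallelic"),
    )
    theta_by_label = {
        "MEG": config.meg_maternal_fraction,
        "PEG": config.peg_maternal_fraction,
        "biallelic": config.null_maternal_fraction,
    }

    lo, hi = config.depth_range
    counts1: list[GeneAllelicCount] = []
    counts2: list[GeneAllelicCount] = []
    truth_labels: dict[str, str] = {}
    truth_theta: dict[str, float] = {}
    truth_depths: dict[str, tuple[int, int]] = {}
    for gene, label in zip(gene_ids, labels):
        theta = theta_by_label[label]
        d1 = int(rng.integers(lo, hi + 1))
        d2 = int(rng.integers(lo, hi + 1))
        m1 = _draw_maternal(rng, d1, theta, config.overdispersion)
        m2 = _draw_maternal(rng, d2, theta, config.overdispersion)
        counts1.append(GeneAllelicCount(gene, COL_X_CVI, m1, d1 - m1, 1))
        counts2.append(GeneAllelicCount(gene, CVI_X_COL, m2, d2 - m2, 1))
        truth_labels[gene] = str(label)
        truth_theta[gene] = theta
        truth_depths[gene] = (d1, d2)

    truth = SimTruth(labels=truth_labels, maternal_fractions=truth_theta,
                     depths=truth_depths)
    return counts1, counts2, truth


@dataclass(frozen=True)
class ClusterSpec:
    """One planted expression cluster: a centroid profile over the four
    dormancy-ordered genotypes and the share of genes it receives."""

    centroid: tuple[float, float, float, float]
    share: float


DEFAULT_CLUSTER_SPEC: tuple[ClusterSpec, ...] = (
    # rising with falling dormancy (the dormancy-anticorrelated cluster)
    ClusterSpec(centroid=(0.25, 0.5, 1.0, 2.0), share=0.45),
    # flat around the reference
    ClusterSpec(centroid=(1.0, 1.0, 1.0, 1.0), share=0.35),
    # high in the dormant parent, falling
    ClusterSpec(centroid=(4.0, 2.0, 1.0, 0.5), share=0.20),
)


def simulate_expression_panel(
    n_genes: int,
    cluster_spec: Sequence[ClusterSpec] = DEFAULT_CLUSTER_SPEC,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Genotype-ordered expression panel with planted cluster structure.

    Gene profiles are the cluster centroid times multiplicative log-normal
    noise (sigma ``noise_sd`` on the natural-log scale); truth labels map
    each gene to its generating cluster (1-based, in spec order).
    """
    shares = [c.share for c in cluster_spec]
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValueError(f"cluster shares must sum to 1, got {sum(shares)}")
    rng = np.random.default_rng(seed)
    sizes = np.floor(np.multiply(shares, n_genes)).astype(int)
    # hand remainders to the largest-share clusters, preserving n_genes
    for i in np.argsort(shares)[::-1][: n_genes - sizes.sum()]:
        sizes[i] += 1

    width = max(4, len(str(n_genes)))
    rows, labels = [], {}
    gene_no = 0
    for ci, (spec, size) in enumerate(zip(cluster_spec, sizes), start=1):
        centroid = np.asarray(spec.centroid, dtype=float)
        for _ in range(size):
            gene_no += 1
            gene = f"ATEXP{gene_no:0{width}d}"
            noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=4) if noise_sd > 0 else 1.0
            rows.append(pd.Series(centroid * noise, index=DORMANCY_ORDER, name=gene))
            labels[gene] = ci
    values = pd.DataFrame(rows)
    metadata = pd.DataFrame(
        {
            "genotype": DORMANCY_ORDER,
            "condition": "control",
            "dormancy_rank": [4, 3, 2, 1],
        },
        index=pd.Index(DORMANCY_ORDER, name="sample"),
    )
    return ExpressionMatrix(values=values, metadata=metadata), labels


def _snps_for_genes(gene_ids: Sequence[str], rng: np.random.Generator) -> list[SnpSite]:
    """One to three diagnostic SNPs per gene, on a toy five-chromosome genome."""
    bases = np.array(list("ACGT"))
    sites = []
    pos = 0
    for idx, gene in enumerate(gene_ids):
        chrom = f"Chr{(idx % 5) + 1}"
        for _ in range(int(rng.integers(1, 4))):
            pos += int(rng.integers(50, 500))
            col, cvi = rng.choice(bases, size=2, replace=False)
            sites.append(SnpSite(chrom, pos, str(col), str(cvi), gene))
    return sites


def write_fixtures(out_dir: str, config: SimConfig | None = None) -> dict[str, str]:
    """Emit the full TSV fixture set used by the readers and the pipeline.

    Writes a SNP table, per-SNP count tables for both crosses (splitting each
    gene's simulated totals across its SNPs), the aggregated gene-count
    tables, an expression panel with metadata, and the truth tables.  Byte
    identical across runs for a fixed config.
    """
    config = config or SimConfig(n_genes=200, frac_meg=0.05, frac_peg=0.02, seed=7)
    os.makedirs(out_dir, exist_ok=True)
    counts1, counts2, truth = simulate_allelic_counts(config)
    rng = np.random.default_rng(config.seed + 1)

    gene_ids = sorted(truth.labels)
    sites = _snps_for_genes(gene_ids, rng)
    by_gene: dict[str, list[SnpSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)

    def per_snp_rows(counts: list[GeneAllelicCount], library_id: str) -> pd.DataFrame:
        rows = []
        for gc in counts:
            gsites = by_gene[gc.gene_id]
            k = len(gsites)
            m_split = rng.multinomial(gc.maternal_reads, [1.0 / k] * k)
            p_split = rng.multinomial(gc.paternal_reads, [1.0 / k] * k)
            for site, m, p in zip(gsites, m_split, p_split):
                col, cvi = (m, p) if gc.cross.mother_is_reference else (p, m)
                rows.append((library_id, site.chrom, site.pos, int(col), int(cvi), 0))
        return pd.DataFrame(rows, columns=[
            "library_id", "chrom", "pos", "col_reads", "cvi_reads", "other_reads"])

    paths = {
        "snp_table": os.path.join(out_dir, "snp_table.tsv"),
        "snp_counts_cross1": os.path.join(out_dir, "snp_counts_ColxCvi.tsv"),
        "snp_counts_cross2": os.path.join(out_dir, "snp_counts_CvixCol.tsv"),
        "gene_counts_cross1": os.path.join(out_dir, "gene_counts_ColxCvi.tsv"),
        "gene_counts_cross2": os.path.join(out_dir, "gene_counts_CvixCol.tsv"),
        "expression_matrix": os.path.join(out_dir, "expression.tsv"),
        "sample_metadata": os.path.join(out_dir, "samples.tsv"),
        "allelic_truth": os.path.join(out_dir, "allelic_truth.tsv"),
        "expression_truth": os.path.join(out_dir, "expression_truth.tsv"),
    }
    write_snp_table(sites, paths["snp_table"])
    per_snp_rows(counts1, "ColxCvi_lib1").to_csv(paths["snp_counts_cross1"], sep="\t", index=False)
    per_snp_rows(counts2, "CvixCol_lib1").to_csv(paths["snp_counts_cross2"], sep="\t", index=False)
    write_gene_counts(counts1, paths["gene_counts_cross1"])
    write_gene_counts(counts2, paths["gene_counts_cross2"])

    panel, panel_labels = simulate_expression_panel(
        n_genes=min(90, config.n_genes), seed=config.seed)
    panel.to_tsv(paths["expression_matrix"], paths["sample_metadata"])
    truth.to_frame().to_csv(paths["allelic_truth"], sep="\t", index=False)
    pd.DataFrame(sorted(panel_labels.items()), columns=["gene_id", "cluster"]).to_csv(
        paths["expression_truth"], sep="\t", index=False)
    return paths
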