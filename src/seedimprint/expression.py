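"""Expression-level analyses downstream of the imprinting calls.

Covers FPKM abundance, relative-expression K-means clustering of the
dormancy-specific MEGs, a monotone dormancy-correlation classifier over the
genotype panel (Cvi, CvixCol, ColxCvi, Col ordered by decreasing seed
dormancy), cold-response classes, a simplified exact-test differential
expression surrogate, and the testa-contamination read-fraction QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: genotypes ordered from most to least dormant seeds
DORMANCY_ORDER = ("Cvi", "CvixCol", "ColxCvi", "Col")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix (FPKM) with per-sample metadata.

    ``metadata`` is indexed by sample and may carry ``genotype``,
    ``condition``, ``dormancy_rank`` and ``library_size`` columns; only the
    analyses that need a column require it.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.metadata.empty:
            missing = set(self.values.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, matrix_path: str, metadata_path: str | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, matrix_path: str, metadata_path: str | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
        metadata = (
            pd.read_csv(metadata_path, sep="\t", index_col="sample")
            if metadata_path is not None
            else pd.DataFrame()
        )
        return cls(values=values, metadata=metadata)


def fpkm(fragment_count: float, exonic_length_bp: float, total_mapped_fragments: float) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if exonic_length_bp <= 0:
        raise ValueError("exonic length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("library size must be positive")
    return fragment_count * 1e9 / (exonic_length_bp * total_mapped_fragments)


def fpkm_matrix(
    counts: pd.DataFrame, exonic_lengths: Mapping[str, float],
    library_sizes: Mapping[str, float],
) -> pd.DataFrame:
    """Vectorised FPKM over a genes x samples fragment-count table."""
    lengths = pd.Series({g: exonic_lengths[g] for g in counts.index}, dtype=float)
    sizes = pd.Series({s: library_sizes[s] for s in counts.columns}, dtype=float)
    if (lengths <= 0).any() or (sizes <= 0).any():
        raise ValueError("exonic lengths and library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(sizes, axis=1)


def relative_to_reference(matrix: ExpressionMatrix, reference_sample: str) -> ExpressionMatrix:
    """Divide every gene's profile by its value in the reference sample.

    Genes with a zero reference value have no defined relative profile and
    are dropped with a logged count.
    """
    if reference_sample not in matrix.values.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    ref = matrix.values[reference_sample]
    keep = ref > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d genes with zero expression in reference %s",
                       n_dropped, reference_sample)
    rel = matrix.values.loc[keep].div(ref.loc[keep], axis=0)
    return ExpressionMatrix(values=rel, metadata=matrix.metadata)


@dataclass(frozen=True)
class ClusterResult:
    assignments: Mapping[str, int]  # gene -> cluster index in 1..k
    k: int
    centroids: np.ndarray  # k x n_samples
    seed: int
    inertia: float


def kmeans_cluster(
    matrix: ExpressionMatrix, k: int = 3, seed: int = 17, restarts: int = 25
) -> ClusterResult:
    """K-means on the gene rows of a (relative) expression matrix.

    Deterministic for fixed ``(seed, restarts)``; the best of ``restarts``
    initialisations by within-cluster sum of squares is kept.  Cluster indices
    are relabelled 1..k in order of first appearance down the gene list, so
    duplicate-row ties always resolve to the lowest index.
    """
    n_genes = len(matrix.values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({n_genes})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(matrix.values.to_numpy())
    # stable relabelling: first gene's cluster becomes 1, next new cluster 2, ...
    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for gene, lab in zip(matrix.values.index, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignments[gene] = relabel[lab]
    order = sorted(relabel, key=relabel.get)
    centroids = km.cluster_centers_[order]
    return ClusterResult(assignments=assignments, k=k, centroids=centroids,
                         seed=seed, inertia=float(km.inertia_))


def dormancy_correlation_class(
    values_by_genotype: Mapping[str, float],
    method: Literal["monotone", "spearman"] = "monotone",
    spearman_threshold: float = -0.8,
) -> Literal["negative", "other"]:
    """Classify one gene's four-genotype profile against the dormancy ranking.

    ``"negative"`` means expression rises as dormancy falls: with genotypes
    ordered most-to-least dormant (Cvi, CvixCol, ColxCvi, Col) the profile is
    strictly increasing.  The Spearman variant instead requires rank
    correlation with the dormancy rank at or below ``spearman_threshold``.
    """
    missing = [g for g in DORMANCY_ORDER if g not in values_by_genotype]
    if missing:
        raise ValueError(f"missing genotype value(s): {missing}")
    profile = [float(values_by_genotype[g]) for g in DORMANCY_ORDER]
    if method == "monotone":
        increasing = all(a < b for a, b in zip(profile, profile[1:]))
        return "negative" if increasing else "other"
    if method == "spearman":
        dormancy_rank = [4, 3, 2, 1]  # Cvi most dormant
        rho = stats.spearmanr(dormancy_rank, profile).statistic
        return "negative" if rho <= spearman_threshold else "other"
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ColdResponseClass:
    gene_id: str
    response: Literal["Down", "Up", "Unchanged"]
    fold_change: float
    pvalue: float


def cold_response_class(
    gene_id: str, expr_control: float, expr_cold: float, pvalue: float
) -> ColdResponseClass:
    """Down / Up / Unchanged by the two-fold, p < 0.05 rule.

    ``expr_cold`` over ``expr_control`` below 0.5 with p < 0.05 is Down;
    above 2 with p < 0.05 is Up; anything else Unchanged.  A zero control
    with non-zero cold expression is Up with an infinite fold change.
    """
    if expr_control < 0 or expr_cold < 0:
        raise ValueError("expression values must be non-negative")
    if expr_control == 0:
        if expr_cold > 0:
            fold = math.inf
            logger.warning("gene %s: zero control expression, infinite fold change", gene_id)
            response = "Up" if pvalue < 0.05 else "Unchanged"
            return ColdResponseClass(gene_id, response, fold, pvalue)
        raise ValueError(f"gene {gene_id}: zero expression in both conditions")
    fold = expr_cold / expr_control
    if fold < 0.5 and pvalue < 0.05:
        response = "Down"
    elif fold > 2.0 and pvalue < 0.05:
        response = "Up"
    else:
        response = "Unchanged"
    return ColdResponseClass(gene_id, response, fold, pvalue)


def de_test(
    counts_a: int, counts_b: int, libsize_a: int, libsize_b: int
) -> tuple[float, float]:
    """Simplified two-library differential expression test.

    Deliberately minimal surrogate for a full DE engine, intended for
    synthetic-data exercises and the cold Down/Up classification: the log2
    ratio of library-size-normalised counts (pseudocount 0.5) plus a
    two-sided Fisher exact p-value on the 2x2 table of in-gene vs rest-of-
    library fragments.  No dispersion modelling across replicates.
    """
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be positive")
    if counts_a > libsize_a or counts_b > libsize_b:
        raise ValueError("gene counts cannot exceed the library size")
    if counts_a < 0 or counts_b < 0:
        raise ValueError("counts must be non-negative")
    log2fc = math.log2(((counts_a + 0.5) / libsize_a) / ((counts_b + 0.5) / libsize_b))
    table = [[counts_a, libsize_a - counts_a], [counts_b, libsize_b - counts_b]]
    pvalue = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return log2fc, pvalue


def contamination_fraction(reads_testa: int, reads_endosperm: int) -> float:
    """Testa reads as a percentage of endosperm-library reads for one gene.

    The testa is dead maternal tissue; a maternally biased transcript truly
    expressed in the endosperm should leave at most a trace in a testa-only
    library, so this percentage is the contamination QC statistic.
    """
    if reads_endosperm <= 0:
        raise ValueError("endosperm read count must be positive")
    if reads_testa < 0:
        raise ValueError("testa read count must be non-negative")
    return 100.0 * reads_testa / reads_endosperm
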