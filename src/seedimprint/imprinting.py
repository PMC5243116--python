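"""MEG/PEG calling from reciprocal-cross allelic counts.

The endosperm is triploid — two maternal genomes and one paternal — so a
biallelically expressed gene is expected to show a 2:1 maternal:paternal read
ratio, not 1:1.  A gene is called imprinted only when its allelic bias clears
a fraction threshold *and* deviates significantly from 2:1 *in both reciprocal
cross directions*; the reciprocal requirement separates imprinting from
accession-specific (cis) expression differences, which follow the allele
rather than the parent.

The caller is organised statsmodels-style: build an :class:`ImprintingModel`
from the two per-cross count tables, ``fit()`` it with a :class:`CallConfig`,
and read estimates, p-values and class labels off the returned
:class:`ImprintingResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import pandas as pd
from scipy import stats

from .allelic import GeneAllelicCount

logger = logging.getLogger(__name__)

CallClass = Literal["MEG", "PEG", "biallelic", "low_reads"]


@dataclass(frozen=True)
class CallConfig:
    """Thresholds of the three-criterion imprinting call.

    meg_fraction_threshold
        Minimum maternal fraction m/(m+p), strict, in both crosses (default 0.8).
    peg_fraction_threshold
        Minimum paternal fraction p/(m+p), strict, in both crosses (default 0.6).
    min_reads
        Per-gene informative read floor per cross; genes below it in either
        cross are reported ``low_reads`` (default 5).
    alpha
        Per-cross significance cutoff of the exact test (default 0.05), applied
        without multiple-testing correction unless ``bh_correction`` is set.
    expected_maternal_ratio
        Null maternal fraction; 2/3 for triploid endosperm.
    test_backend
        ``"fisher"`` (2x2 exact test against a same-total expected row) or
        ``"binomial"`` (exact binomial with success probability 2/3).
    """

    meg_fraction_threshold: float = 0.8
    peg_fraction_threshold: float = 0.6
    min_reads: int = 5
    alpha: float = 0.05
    expected_maternal_ratio: float = 2.0 / 3.0
    test_backend: Literal["fisher", "binomial"] = "fisher"
    bh_correction: bool = False

    def __post_init__(self) -> None:
        for name in ("meg_fraction_threshold", "peg_fraction_threshold", "alpha",
                     "expected_maternal_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


@dataclass(frozen=True)
class ImprintingCall:
    gene_id: str
    call: CallClass
    maternal_fraction_cross1: float
    maternal_fraction_cross2: float
    pvalue_cross1: float
    pvalue_cross2: float


@dataclass(frozen=True)
class ImprintingSets:
    """MEG and PEG gene sets for one condition (e.g. dormant / non-dormant)."""

    megs: frozenset[str]
    pegs: frozenset[str]
    condition: str = ""

    def __post_init__(self) -> None:
        if self.megs & self.pegs:
            raise ValueError("a gene cannot be both MEG and PEG")


def maternal_fraction(count: GeneAllelicCount) -> float:
    """Maternal reads over informative reads for one gene in one cross."""
    total = count.total
    if total == 0:
        raise ValueError(f"gene {count.gene_id}: zero informative reads, fraction undefined")
    return count.maternal_reads / total


def _expected_row(total: int, expected_maternal_ratio: float) -> tuple[int, int]:
    # round half up; 2N/3 is never exactly half-integral but the config ratio
    # is free, so be explicit
    expected_m = math.floor(total * expected_maternal_ratio + 0.5)
    return expected_m, total - expected_m


def fisher_vs_expected(
    maternal_reads: int,
    paternal_reads: int,
    expected_maternal_ratio: float = 2.0 / 3.0,
) -> float:
    """Two-tailed Fisher exact p-value of (m, p) against an expected row with
    the same total split at the null maternal ratio."""
    if maternal_reads < 0 or paternal_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = maternal_reads + paternal_reads
    if total < 1:
        raise ValueError("need at least one informative read")
    exp_m, exp_p = _expected_row(total, expected_maternal_ratio)
    table = [[maternal_reads, paternal_reads], [exp_m, exp_p]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def binomial_vs_expected(
    maternal_reads: int,
    paternal_reads: int,
    expected_maternal_ratio: float = 2.0 / 3.0,
) -> float:
    """Exact two-sided binomial test of the maternal count against the null
    maternal probability; alternative backend to :func:`fisher_vs_expected`."""
    if maternal_reads < 0 or paternal_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = maternal_reads + paternal_reads
    if total < 1:
        raise ValueError("need at least one informative read")
    return float(stats.binomtest(maternal_reads, total, expected_maternal_ratio).pvalue)


def log_ratio_duplicated_paternal(
    maternal_reads: int, paternal_reads: int, pseudocount: float = 0.0
) -> float:
    """log2 of maternal reads over *duplicated* paternal reads.

    Doubling the paternal count puts the triploid 2:1 null at zero, so the
    genome-wide distribution of this statistic should centre at 0 for
    biallelic genes; MEGs sit far right, PEGs far left.
    """
    if maternal_reads < 0 or paternal_reads < 0:
        raise ValueError("read counts must be non-negative")
    num = maternal_reads + pseudocount
    den = 2.0 * paternal_reads + pseudocount
    if num == 0.0 or den == 0.0:
        raise ValueError("log ratio undefined for zero counts without a pseudocount")
    return math.log2(num / den)


def call_gene(
    count_cross1: GeneAllelicCount,
    count_cross2: GeneAllelicCount,
    config: CallConfig | None = None,
) -> ImprintingCall:
    """Classify one gene from its two reciprocal-cross count records.

    Order of criteria: the read floor first (``low_reads`` short-circuits, its
    fractions/p-values reported as NaN where undefined), then the fraction
    thresholds in both crosses, then per-cross exact-test significance.
    """
    config = config or CallConfig()
    if count_cross1.gene_id != count_cross2.gene_id:
        raise ValueError(
            f"mismatched gene ids: {count_cross1.gene_id} vs {count_cross2.gene_id}"
        )
    if count_cross1.cross == count_cross2.cross:
        raise ValueError(f"gene {count_cross1.gene_id}: need opposite cross directions")

    if count_cross1.total < config.min_reads or count_cross2.total < config.min_reads:
        fracs = [
            maternal_fraction(c) if c.total > 0 else math.nan
            for c in (count_cross1, count_cross2)
        ]
        return ImprintingCall(count_cross1.gene_id, "low_reads", fracs[0], fracs[1],
                              math.nan, math.nan)

    test = fisher_vs_expected if config.test_backend == "fisher" else binomial_vs_expected
    f1 = maternal_fraction(count_cross1)
    f2 = maternal_fraction(count_cross2)
    p1 = test(count_cross1.maternal_reads, count_cross1.paternal_reads,
              config.expected_maternal_ratio)
    p2 = test(count_cross2.maternal_reads, count_cross2.paternal_reads,
              config.expected_maternal_ratio)

    significant = p1 < config.alpha and p2 < config.alpha
    call: CallClass = "biallelic"
    if f1 > config.meg_fraction_threshold and f2 > config.meg_fraction_threshold and significant:
        call = "MEG"
    elif ((1.0 - f1) > config.peg_fraction_threshold
          and (1.0 - f2) > config.peg_fraction_threshold and significant):
        call = "PEG"
    return ImprintingCall(count_cross1.gene_id, call, f1, f2, p1, p2)


class ImprintingModel:
    """Reciprocal-cross imprinting caller over a full gene table.

    Parameters
    ----------
    counts_cross1, counts_cross2
        Per-gene allelic counts for the two reciprocal cross directions.
        Genes present in only one direction are uncallable and dropped with a
        logged count (available as ``n_single_cross``).
    condition
        Free-text condition label carried into the result sets (e.g.
        ``"dormant"``).
    """

    def __init__(
        self,
        counts_cross1: Sequence[GeneAllelicCount],
        counts_cross2: Sequence[GeneAllelicCount],
        condition: str = "",
    ) -> None:
        by1 = {c.gene_id: c for c in counts_cross1}
        by2 = {c.gene_id: c for c in counts_cross2}
        shared = sorted(by1.keys() & by2.keys())
        self.n_single_cross = len(by1.keys() ^ by2.keys())
        if self.n_single_cross:
            logger.info("%d genes detected in only one cross direction: uncallable",
                        self.n_single_cross)
        self._pairs = [(by1[g], by2[g]) for g in shared]
        self.condition = condition

    @classmethod
    def from_frames(cls, frame1: pd.DataFrame, frame2: pd.DataFrame,
                    condition: str = "") -> "ImprintingModel":
        """Build from two gene-count DataFrames with the standard columns
        ``gene_id cross maternal_reads paternal_reads n_snps``."""
        from .allelic import CrossDirection

        def to_counts(df: pd.DataFrame) -> list[GeneAllelicCount]:
            return [
                GeneAllelicCount(str(r.gene_id), CrossDirection.from_label(str(r.cross)),
                                 int(r.maternal_reads), int(r.paternal_reads), int(r.n_snps))
                for r in df.itertuples(index=False)
            ]

        return cls(to_counts(frame1), to_counts(frame2), condition=condition)

    @property
    def n_genes(self) -> int:
        return len(self._pairs)

    def fit(self, config: CallConfig | None = None) -> "ImprintingResults":
        config = config or CallConfig()
        calls = [call_gene(c1, c2, config) for c1, c2 in self._pairs]
        if config.bh_correction:
            calls = _apply_bh(calls, config)
        return ImprintingResults(self, config, calls)


def _apply_bh(calls: list[ImprintingCall], config: CallConfig) -> list[ImprintingCall]:
    """Optional Benjamini-Hochberg pass: re-evaluate significance on BH-adjusted
    per-cross p-values, demoting MEG/PEG calls that no longer clear alpha."""
    from statsmodels.stats.multitest import multipletests

    tested = [c for c in calls if c.call != "low_reads"]
    if not tested:
        return calls
    adj1 = multipletests([c.pvalue_cross1 for c in tested], method="fdr_bh")[1]
    adj2 = multipletests([c.pvalue_cross2 for c in tested], method="fdr_bh")[1]
    adjusted = {}
    for c, a1, a2 in zip(tested, adj1, adj2):
        new_call = c.call
        if c.call in ("MEG", "PEG") and not (a1 < config.alpha and a2 < config.alpha):
            new_call = "biallelic"
        adjusted[c.gene_id] = replace(c, call=new_call, pvalue_cross1=float(a1),
                                      pvalue_cross2=float(a2))
    return [adjusted.get(c.gene_id, c) for c in calls]


class ImprintingResults:
    """Fitted call table plus the MEG/PEG sets and summary tallies."""

    def __init__(self, model: ImprintingModel, config: CallConfig,
                 calls: Sequence[ImprintingCall]) -> None:
        self.model = model
        self.config = config
        self.calls = list(calls)

    @property
    def sets(self) -> ImprintingSets:
        return ImprintingSets(
            megs=frozenset(c.gene_id for c in self.calls if c.call == "MEG"),
            pegs=frozenset(c.gene_id for c in self.calls if c.call == "PEG"),
            condition=self.model.condition,
        )

    def class_counts(self) -> dict[str, int]:
        counts = {"MEG": 0, "PEG": 0, "biallelic": 0, "low_reads": 0}
        for c in self.calls:
            counts[c.call] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.gene_id, c.call, c.maternal_fraction_cross1, c.maternal_fraction_cross2,
                 c.pvalue_cross1, c.pvalue_cross2)
                for c in self.calls
            ],
            columns=["gene_id", "call", "maternal_fraction_cross1",
                     "maternal_fraction_cross2", "pvalue_cross1", "pvalue_cross2"],
        )

    def summary(self) -> str:
        counts = self.class_counts()
        cond = f" ({self.model.condition})" if self.model.condition else ""
        lines = [
            f"Imprinting call summary{cond}",
            "=" * 40,
            f"genes callable in both crosses : {self.model.n_genes}",
            f"genes in one cross only        : {self.model.n_single_cross}",
            f"MEGs                           : {counts['MEG']}",
            f"PEGs                           : {counts['PEG']}",
            f"biallelic                      : {counts['biallelic']}",
            f"below read floor ({self.config.min_reads:>3} reads)   : {counts['low_reads']}",
            "-" * 40,
            f"MEG maternal fraction > {self.config.meg_fraction_threshold}, "
            f"PEG paternal fraction > {self.config.peg_fraction_threshold}",
            f"{self.config.test_backend} exact test vs 2:1, alpha = {self.config.alpha}"
            + (", BH-corrected" if self.config.bh_correction else ""),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class ConditionPartition:
    """Condition-specific / shared split of one gene class across two conditions."""

    specific_first: frozenset[str]
    shared: frozenset[str]
    specific_second: frozenset[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.specific_first), len(self.shared), len(self.specific_second)


def classify_condition_specific(
    sets_first: ImprintingSets, sets_second: ImprintingSets
) -> dict[str, ConditionPartition]:
    """Partition MEGs and PEGs (separately) into first-condition-specific,
    shared, and second-condition-specific sets."""
    out = {}
    for name in ("megs", "pegs"):
        a: frozenset[str] = getattr(sets_first, name)
        b: frozenset[str] = getattr(sets_second, name)
        out[name] = ConditionPartition(
            specific_first=a - b, shared=a & b, specific_second=b - a
        )
    return out
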