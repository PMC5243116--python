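"""Per-SNP allele counts and their aggregation to per-gene maternal/paternal totals.

A reciprocal-cross design distinguishes the two parental genomes (here the
Col reference accession and the Cvi alternate accession) at diagnostic exonic
SNPs.  Reads overlapping a SNP are assigned to one parent or the other; which
parent is *maternal* depends on the direction of the cross, so orientation is
a property of the library, not of the SNP table.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

SNP_TABLE_COLUMNS = ["chrom", "pos", "col_allele", "cvi_allele", "gene_id"]
SNP_COUNT_COLUMNS = ["library_id", "chrom", "pos", "col_reads", "cvi_reads", "other_reads"]
GENE_COUNT_COLUMNS = ["gene_id", "cross", "maternal_reads", "paternal_reads", "n_snps"]


class SnpTableError(ValueError):
    """Malformed or inconsistent SNP table input."""


@dataclass(frozen=True, order=True)
class SnpSite:
    """One diagnostic polymorphism: genomic position, the two parental alleles
    and the gene it falls in."""

    chrom: str
    pos: int
    col_allele: str
    cvi_allele: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SnpTableError(f"pos must be >= 1 (1-based coordinates), got {self.pos}")
        if self.col_allele not in _NUCLEOTIDES or self.cvi_allele not in _NUCLEOTIDES:
            raise SnpTableError(
                f"alleles must be single nucleotides in A/C/G/T, got "
                f"{self.col_allele!r}/{self.cvi_allele!r} at {self.chrom}:{self.pos}"
            )
        if self.col_allele == self.cvi_allele:
            raise SnpTableError(
                f"parental alleles must differ at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class SnpAlleleCount:
    """Read counts at one SNP in one library.

    ``other_reads`` are bases matching neither parental allele; they are kept
    for QC but never enter maternal/paternal totals.
    """

    site: SnpSite
    col_reads: int
    cvi_reads: int
    other_reads: int = 0
    library_id: str = ""

    def __post_init__(self) -> None:
        if min(self.col_reads, self.cvi_reads, self.other_reads) < 0:
            raise ValueError("allele counts must be non-negative")


@dataclass(frozen=True)
class CrossDirection:
    """A cross written mother x father.  The maternal allele of every SNP is
    the Col allele when the mother is the reference accession, else the Cvi
    allele."""

    mother: str
    father: str

    _KNOWN = frozenset({"Col", "Cvi"})

    def __post_init__(self) -> None:
        if self.mother == self.father:
            raise ValueError("mother and father genotypes must differ")
        unknown = {self.mother, self.father} - self._KNOWN
        if unknown:
            raise ValueError(
                f"unknown parental genotype label(s) {sorted(unknown)}; expected Col/Cvi"
            )

    @property
    def label(self) -> str:
        return f"{self.mother}x{self.father}"

    @classmethod
    def from_label(cls, label: str) -> "CrossDirection":
        parts = label.split("x")
        if len(parts) != 2:
            raise ValueError(f"cross label must look like 'ColxCvi', got {label!r}")
        return cls(mother=parts[0], father=parts[1])

    @property
    def mother_is_reference(self) -> bool:
        return self.mother == "Col"


COL_X_CVI = CrossDirection("Col", "Cvi")
CVI_X_COL = CrossDirection("Cvi", "Col")


@dataclass(frozen=True)
class GeneAllelicCount:
    """Maternal/paternal read totals for one gene in one cross direction,
    summed over the gene's covered SNPs."""

    gene_id: str
    cross: CrossDirection
    maternal_reads: int
    paternal_reads: int
    n_snps: int

    def __post_init__(self) -> None:
        if min(self.maternal_reads, self.paternal_reads) < 0:
            raise ValueError("read totals must be non-negative")
        if self.n_snps < 1:
            raise ValueError("an emitted gene count must cover at least one SNP")

    @property
    def total(self) -> int:
        return self.maternal_reads + self.paternal_reads


# ---------------------------------------------------------------------------
# readers / writers


def _validate_sites(rows: Iterable[tuple[int, SnpSite]]) -> list[SnpSite]:
    seen: dict[tuple[str, int], SnpSite] = {}
    for lineno, site in rows:
        key = (site.chrom, site.pos)
        prev = seen.get(key)
        if prev is not None:
            if (prev.col_allele, prev.cvi_allele) != (site.col_allele, site.cvi_allele):
                raise SnpTableError(
                    f"line {lineno}: duplicate site {site.chrom}:{site.pos} with "
                    f"conflicting alleles"
                )
            continue  # exact duplicate rows are collapsed
        seen[key] = site
    return sorted(seen.values())


def read_snp_table(source: Union[str, io.TextIOBase], dialect: str = "tsv") -> list[SnpSite]:
    """Parse a SNP table into validated, de-duplicated sites sorted by position.

    ``dialect='tsv'`` expects a header ``chrom pos col_allele cvi_allele gene_id``;
    ``dialect='vcf'`` expects VCF-like columns CHROM/POS/REF/ALT with the host
    gene in an ``INFO`` field tag ``GENE=``.
    """
    if dialect not in {"tsv", "vcf"}:
        raise ValueError(f"unknown SNP table dialect {dialect!r}")
    handle = open(source) if isinstance(source, str) else source
    try:
        rows: list[tuple[int, SnpSite]] = []
        if dialect == "tsv":
            header = handle.readline().rstrip("\n").split("\t")
            if header[:5] != SNP_TABLE_COLUMNS:
                raise SnpTableError(
                    f"line 1: expected header {SNP_TABLE_COLUMNS}, got {header}"
                )
            for lineno, line in enumerate(handle, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 5:
                    raise SnpTableError(f"line {lineno}: expected 5 columns, got {len(fields)}")
                chrom, pos_s, col_a, cvi_a, gene = fields
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise SnpTableError(f"line {lineno}: non-integer pos {pos_s!r}") from exc
                try:
                    rows.append((lineno, SnpSite(chrom, pos, col_a, cvi_a, gene)))
                except SnpTableError as exc:
                    raise SnpTableError(f"line {lineno}: {exc}") from exc
        else:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    raise SnpTableError(f"line {lineno}: VCF row needs >= 8 columns")
                chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
                info = fields[7]
                gene = ""
                for item in info.split(";"):
                    if item.startswith("GENE="):
                        gene = item[5:]
                if not gene:
                    raise SnpTableError(f"line {lineno}: missing GENE= tag in INFO")
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise SnpTableError(f"line {lineno}: non-integer POS {pos_s!r}") from exc
                try:
                    rows.append((lineno, SnpSite(chrom, pos, ref, alt, gene)))
                except SnpTableError as exc:
                    raise SnpTableError(f"line {lineno}: {exc}") from exc
        return _validate_sites(rows)
    finally:
        if isinstance(source, str):
            handle.close()


def write_snp_table(sites: Sequence[SnpSite], path: str) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.pos, s.col_allele, s.cvi_allele, s.gene_id) for s in sorted(sites)],
        columns=SNP_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_snp_counts(source: Union[str, io.TextIOBase], snp_table: Sequence[SnpSite]) -> list[SnpAlleleCount]:
    """Read per-SNP count rows (``library_id chrom pos col_reads cvi_reads other_reads``),
    joining each row to its site.  Rows at positions absent from the SNP table
    are skipped with a logged count."""
    by_pos = {(s.chrom, s.pos): s for s in snp_table}
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str, "library_id": str})
    missing = [c for c in SNP_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SnpTableError(f"per-SNP count table missing columns {missing}")
    counts: list[SnpAlleleCount] = []
    skipped = 0
    for row in df.itertuples(index=False):
        site = by_pos.get((row.chrom, int(row.pos)))
        if site is None:
            skipped += 1
            continue
        counts.append(
            SnpAlleleCount(
                site=site,
                col_reads=int(row.col_reads),
                cvi_reads=int(row.cvi_reads),
                other_reads=int(row.other_reads),
                library_id=str(row.library_id),
            )
        )
    if skipped:
        logger.warning("skipped %d per-SNP count records at positions absent from the SNP table", skipped)
    return counts


def gene_counts_to_frame(counts: Sequence[GeneAllelicCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.gene_id, c.cross.label, c.maternal_reads, c.paternal_reads, c.n_snps)
            for c in counts
        ],
        columns=GENE_COUNT_COLUMNS,
    )


def write_gene_counts(counts: Sequence[GeneAllelicCount], path: str) -> None:
    gene_counts_to_frame(counts).to_csv(path, sep="\t", index=False)


def read_gene_counts(source: Union[str, io.TextIOBase]) -> list[GeneAllelicCount]:
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in GENE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SnpTableError(f"gene count table missing columns {missing}")
    return [
        GeneAllelicCount(
            gene_id=str(r.gene_id),
            cross=CrossDirection.from_label(str(r.cross)),
            maternal_reads=int(r.maternal_reads),
            paternal_reads=int(r.paternal_reads),
            n_snps=int(r.n_snps),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# core operations


def intersect_snp_sets(called: Sequence[SnpSite], reference: Sequence[SnpSite]) -> list[SnpSite]:
    """Keep called sites that also appear in a reference list with identical
    position and alleles.  The gene annotation of the *called* list wins."""
    ref_keys = {(s.chrom, s.pos, s.col_allele, s.cvi_allele) for s in reference}
    return sorted(
        s for s in called if (s.chrom, s.pos, s.col_allele, s.cvi_allele) in ref_keys
    )


def orient_counts(count: SnpAlleleCount, cross: CrossDirection) -> tuple[int, int]:
    """Map (col_reads, cvi_reads) to (maternal_reads, paternal_reads) for a
    library of the given cross direction.  ``other_reads`` are dropped here."""
    if cross.mother_is_reference:
        return count.col_reads, count.cvi_reads
    return count.cvi_reads, count.col_reads


def aggregate_gene_counts(
    counts: Sequence[SnpAlleleCount], cross: CrossDirection
) -> list[GeneAllelicCount]:
    """Sum oriented per-SNP counts over each gene's SNPs.

    Genes with no covered SNP are simply absent from the output.  A site whose
    ``gene_id`` lists several loci separated by commas contributes to each.
    """
    maternal: dict[str, int] = {}
    paternal: dict[str, int] = {}
    n_snps: dict[str, int] = {}
    multi_gene = 0
    for count in counts:
        m, p = orient_counts(count, cross)
        genes = count.site.gene_id.split(",")
        if len(genes) > 1:
            multi_gene += 1
        for gene in genes:
            maternal[gene] = maternal.get(gene, 0) + m
            paternal[gene] = paternal.get(gene, 0) + p
            n_snps[gene] = n_snps.get(gene, 0) + 1
    if multi_gene:
        logger.warning("%d SNP records assigned to multiple overlapping genes", multi_gene)
    return [
        GeneAllelicCount(gene, cross, maternal[gene], paternal[gene], n_snps[gene])
        for gene in sorted(maternal)
    ]
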