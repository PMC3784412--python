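"""Coordinate backbone: genes, intervals, genome ordering, overlap resolution.

Coordinates are 0-based half-open internally.  Printed gene tables (and the
annotation reader's default) use the 1-based inclusive convention common in
journal tables and Ensembl exports; readers convert on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

STRANDS = ("+", "-", "unknown")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def span(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (printed-table convention)."""
        return cls(chrom, start - 1, end)


@dataclass(frozen=True)
class Gene:
    """A probed or unprobed transcript-level locus.

    Strand is carried for bookkeeping but ignored by every score: all region
    computations use the strand-agnostic span from transcription start to
    transcription end.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str = "unknown"
    probed: bool = True

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Ordered collection of genes plus chromosome sizes.

    After :func:`order_genes`, genes are sorted by (start, end) within each
    chromosome and each gene has a per-chromosome index position (the "gene
    index" used when plotting scores along chromosomes).
    """

    genes: list[Gene] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            seen.add(g.gene_id)
        for g in self.genes:
            size = self.chrom_sizes.get(g.interval.chrom)
            if size is not None and g.interval.end > size:
                raise ValueError(
                    f"gene {g.gene_id} extends past chromosome {g.interval.chrom} "
                    f"({g.interval.end} > {size})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for g in self.genes:
            if g.interval.chrom not in out:
                out.append(g.interval.chrom)
        return out

    def by_chromosome(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.interval.chrom == chrom]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def probed_only(self) -> "GenomeAnnotation":
        return GenomeAnnotation([g for g in self.genes if g.probed], dict(self.chrom_sizes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "symbol": [g.symbol for g in self.genes],
                "chrom": [g.interval.chrom for g in self.genes],
                "start": [g.interval.start for g in self.genes],
                "end": [g.interval.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "probed": [g.probed for g in self.genes],
            }
        )


def order_genes(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Sort genes by genome location: chromosome, then (start, end), stably.

    Chromosome blocks keep their first-appearance order so that synthetic and
    real chromosome namings both round-trip deterministically.  Idempotent.
    """
    chrom_rank = {c: i for i, c in enumerate(annotation.chromosomes)}
    ordered = sorted(
        annotation.genes,
        key=lambda g: (chrom_rank[g.interval.chrom], g.interval.start, g.interval.end),
    )
    return GenomeAnnotation(ordered, dict(annotation.chrom_sizes))


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two half-open intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_span(iv: GenomicInterval, *, one_based: bool = False) -> int:
    """Interval length in bp.

    With ``one_based=True`` the interval is interpreted as carrying printed
    1-based inclusive endpoints verbatim (span = end - start + 1); half-open
    intervals built through :meth:`GenomicInterval.from_one_based` already
    account for this and should use the default.
    """
    return iv.span + 1 if one_based else iv.span


def format_kb(span_bp: int, *, decimals: int = 1, integer_from_kb: float = 1000.0) -> str:
    """Format a bp span the way journal tables print sizes in KB.

    Spans below ``integer_from_kb`` KB get ``decimals`` decimal places; larger
    spans are rounded to the nearest integer KB with a thousands separator.
    Rounding is half-away-from-zero, matching hand-rounded tables.
    """
    kb = span_bp / 1000.0
    if kb < integer_from_kb:
        q = 10 ** decimals
        val = int(kb * q + 0.5) / q
        return f"{val:.{decimals}f}"
    return f"{int(kb + 0.5):,}"


def span_kb(span_bp: int, *, decimals: int = 1, integer_from_kb: float = 1000.0) -> float:
    """Numeric KB size at printed precision (the number behind :func:`format_kb`)."""
    kb = span_bp / 1000.0
    if kb < integer_from_kb:
        q = 10 ** decimals
        return int(kb * q + 0.5) / q
    return float(int(kb + 0.5))


def _present_counts(matrix) -> Mapping[str, int]:
    # Lazy import to avoid a cycle; matrix is an expression.ExpressionMatrix.
    return (matrix.calls == "P").sum(axis=1).to_dict()


def resolve_overlaps(annotation: GenomeAnnotation, matrix) -> GenomeAnnotation:
    """Collapse groups of transitively overlapping genes to one representative.

    Genes on the same chromosome whose intervals overlap (transitively: a chain
    A-B, B-C puts A, B, C in one group even if A and C are disjoint) are reduced
    to a single survivor.  The survivor is the gene with the most Present
    detection calls in ``matrix``; ties go to the longest interval, then the
    lexicographically smallest gene_id.  Genes absent from the matrix count as
    zero Present calls.  Requires an ordered annotation.
    """
    p_counts = _present_counts(matrix) if matrix is not None else {}
    survivors: list[Gene] = []
    for chrom in annotation.chromosomes:
        genes = annotation.by_chromosome(chrom)
        group: list[Gene] = []
        group_end = -1
        for g in genes:
            if group and g.interval.start < group_end:
                group.append(g)
                group_end = max(group_end, g.interval.end)
            else:
                if group:
                    survivors.append(_pick_representative(group, p_counts))
                group = [g]
                group_end = g.interval.end
        if group:
            survivors.append(_pick_representative(group, p_counts))
    return order_genes(GenomeAnnotation(survivors, dict(annotation.chrom_sizes)))


def _pick_representative(group: Sequence[Gene], p_counts: Mapping[str, int]) -> Gene:
    def key(g: Gene):
        return (-p_counts.get(g.gene_id, 0), -g.interval.span, g.gene_id)

    return min(group, key=key)


# ---------------------------------------------------------------------------
# Readers


def read_annotation(
    path, *, one_based: bool = True, probed_ids: Iterable[str] | None = None
) -> GenomeAnnotation:
    """Read a gene annotation TSV: gene_id, symbol, chrom, start, end, strand.

    ``one_based=True`` (default) interprets start/end as 1-based inclusive, the
    convention of printed tables and Ensembl-derived exports; pass ``False``
    for BED-derived 0-based half-open input.  ``probed_ids`` restricts the
    probed flag to the listed genes (default: all probed).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    probed = set(probed_ids) if probed_ids is not None else None
    genes = []
    for row in df.itertuples(index=False):
        iv = (
            GenomicInterval.from_one_based(row.chrom, int(row.start), int(row.end))
            if one_based
            else GenomicInterval(row.chrom, int(row.start), int(row.end))
        )
        strand = getattr(row, "strand", "unknown")
        if strand not in STRANDS:
            strand = "unknown"
        genes.append(
            Gene(
                gene_id=str(row.gene_id),
                symbol=str(getattr(row, "symbol", row.gene_id)),
                interval=iv,
                strand=strand,
                probed=(probed is None or str(row.gene_id) in probed),
            )
        )
    return GenomeAnnotation(genes)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (UCSC dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_annotation(annotation: GenomeAnnotation, path, *, one_based: bool = True) -> None:
    df = annotation.to_frame()
    if one_based:
        df["start"] = df["start"] + 1
    df.to_csv(path, sep="\t", index=False)
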