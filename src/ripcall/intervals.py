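"""Core genomic containers shared across the pipeline.

All coordinates are 0-based half-open ``[start, end)`` on a named
chromosome, the BED convention; GTF input is converted at the I/O
boundary.  Two intervals overlap when they share at least one base,
i.e. ``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

VALID_STRANDS = ("+", "-", ".")

#: biotype labels used throughout; anything unrecognised maps to other_ncRNA
BIOTYPES = ("mRNA", "lncRNA", "other_ncRNA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start (bp).
    end : int
        Exclusive end (bp); ``end > start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def strands_compatible(self, other: "GenomicInterval") -> bool:
        """Unstranded ('.') matches either strand."""
        return (
            self.strand == "."
            or other.strand == "."
            or self.strand == other.strand
        )

    def overlaps(self, other: "GenomicInterval", *, stranded: bool = False) -> bool:
        """True when the intervals share >= 1 bp (half-open semantics)."""
        if self.chrom != other.chrom:
            return False
        if stranded and not self.strands_compatible(other):
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped read, reduced to its genomic footprint."""

    interval: GenomicInterval
    read_id: str
    sample: str = ""


@dataclass(frozen=True)
class GeneModel:
    """A gene: span, merged exon structure and biotype.

    ``exons`` is the transcript-merged exon union, sorted and
    non-overlapping, each contained in the gene span.  ``cds`` (mRNA
    only) lists CDS sub-intervals contained in the exon union; exonic
    mRNA bases outside the CDS are UTR, split into 5' and 3' by strand.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "other_ncRNA"
    exons: tuple = ()
    cds: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = exon.end
        if self.cds:
            if self.biotype != "mRNA":
                raise ValueError(f"{self.gene_id}: CDS on non-mRNA gene")
            for c in self.cds:
                if not any(
                    c.start >= e.start and c.end <= e.end for e in self.exons
                ):
                    raise ValueError(f"{self.gene_id}: CDS outside exon union")

    @property
    def span_length(self) -> int:
        return self.interval.length

    @property
    def exon_union_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, within the span."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(
                        self.interval.chrom, a.end, b.start, self.interval.strand
                    )
                )
        return out


@dataclass
class Peak:
    """A cluster of transitively overlapping reads.

    ``height`` is the maximum per-base read coverage inside the peak;
    ``p_value`` is the empirical permutation p (None for intergenic
    peaks, which have no per-gene null).
    """

    interval: GenomicInterval
    peak_id: str
    height: int
    read_count: int
    gene_id: str = "intergenic"
    p_value: Optional[float] = None
    selected: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.height <= self.read_count):
            raise ValueError(
                f"{self.peak_id}: height {self.height} outside [1, {self.read_count}]"
            )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.peak_id}: p-value {self.p_value} outside [0,1]")


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals into their disjoint union.

    Touching (adjacent) intervals are merged; strand is kept when all
    members agree, else '.'.
    """
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strands = {ivs[0].strand}
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
                strands.add(iv.strand)
            else:
                merged.append(
                    GenomicInterval(
                        chrom, cur_start, cur_end,
                        strands.pop() if len(strands) == 1 else ".",
                    )
                )
                cur_start, cur_end = iv.start, iv.end
                strands = {iv.strand}
        merged.append(
            GenomicInterval(
                chrom, cur_start, cur_end,
                strands.pop() if len(strands) == 1 else ".",
            )
        )
    return merged
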