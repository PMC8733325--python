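"""Readers and writers for the formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open.  BED is read
natively; GTF (1-based inclusive) is converted at this boundary and
converted back on write, so a GTF -> internal -> GTF round trip
preserves the printed coordinates exactly.

Peaks are written as BED6+3: chrom, start, end, peak_id, height,
strand, read_count, p_value, gene_id, sorted by (chrom, start).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import AlignedRead, GeneModel, GenomicInterval, Peak, merge_intervals

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike, sample: str = "") -> list[AlignedRead]:
    """Read aligned-read intervals from a BED3-6 file.

    Column 4 (name) becomes the read id (auto-numbered when absent);
    column 6 (strand) is used when present, else '.'.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") \
                else f"read_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            reads.append(
                AlignedRead(GenomicInterval(chrom, start, end, strand), name, sample)
            )
    return reads


def write_bed(reads: Iterable[AlignedRead], path: PathLike) -> None:
    """Write reads as BED6 (score column 0), sorted by (chrom, start)."""
    rows = sorted(reads, key=lambda r: (r.interval.chrom, r.interval.start,
                                        r.interval.end, r.read_id))
    with open(path, "w") as fh:
        for r in rows:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

#: attribute keys probed, in order, for a biotype
BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype", "transcript_biotype")

_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mrna": "mRNA",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "long_noncoding": "lncRNA",
}


def _normalise_biotype(raw: Optional[str]) -> str:
    if raw is None:
        return "other_ncRNA"
    return _BIOTYPE_MAP.get(raw.lower(), raw if raw in ("mRNA", "lncRNA") else "other_ncRNA")


def read_gtf(path: PathLike) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Exons of all transcripts of a gene are merged into their union; the
    gene span is taken from a ``gene`` feature line when present, else
    from the exon extent.  1-based inclusive coordinates become 0-based
    half-open.  Genes without a recognised biotype attribute are
    labelled ``other_ncRNA``.
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    biotypes: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            try:
                iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if gene_id not in order:
                order.append(gene_id)
            raw_bt = next((attr[k] for k in BIOTYPE_KEYS if k in attr), None)
            if raw_bt is not None and gene_id not in biotypes:
                biotypes[gene_id] = _normalise_biotype(raw_bt)
            if feature == "gene":
                spans[gene_id] = iv
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(gene_id, []).append(iv)

    genes: list[GeneModel] = []
    for gene_id in order:
        gene_exons = merge_intervals(exons.get(gene_id, []))
        if gene_id in spans:
            span = spans[gene_id]
        elif gene_exons:
            span = GenomicInterval(
                gene_exons[0].chrom, gene_exons[0].start, gene_exons[-1].end,
                gene_exons[0].strand,
            )
        else:
            continue  # transcript-only entry with no exons and no gene line
        if not gene_exons:
            gene_exons = [span]
        biotype = biotypes.get(gene_id, "other_ncRNA")
        gene_cds = merge_intervals(cds[gene_id]) if gene_id in cds else None
        if gene_cds is not None and biotype != "mRNA":
            biotype = "mRNA"  # CDS implies coding
        genes.append(
            GeneModel(gene_id, span, biotype, tuple(gene_exons),
                      tuple(gene_cds) if gene_cds else None)
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: PathLike,
              source: str = "ripcall") -> None:
    """Write gene models as GTF (1-based inclusive coordinates)."""
    _BT_OUT = {"mRNA": "protein_coding", "lncRNA": "lncRNA",
               "other_ncRNA": "other_ncRNA"}
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            attrs = (f'gene_id "{g.gene_id}"; gene_biotype "{_BT_OUT[g.biotype]}";')
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{iv.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
            for c in g.cds or ():
                fh.write(
                    f"{iv.chrom}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{iv.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Peaks (BED6+3)
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ("chrom", "start", "end", "peak_id", "height", "strand",
                "read_count", "p_value", "gene_id")


def write_peaks(peaks: Iterable[Peak], path: PathLike) -> None:
    """Write peaks as BED6+3, deterministically sorted by (chrom, start)."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start,
                                        p.interval.end, p.peak_id))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            pval = "NA" if p.p_value is None else repr(p.p_value)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{p.height}\t"
                f"{iv.strand}\t{p.read_count}\t{pval}\t{p.gene_id}\n"
            )


def read_peaks(path: PathLike) -> list[Peak]:
    """Read peaks written by :func:`write_peaks`."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            chrom, start, end, peak_id, height, strand, n_reads, pval, gene_id = fields
            peaks.append(
                Peak(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    peak_id,
                    int(height),
                    int(n_reads),
                    gene_id,
                    None if pval == "NA" else float(pval),
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_chrom_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"]))


def read_ct_table(path: PathLike) -> pd.DataFrame:
    """Ct table: sample_id, group, target_ct, reference_ct (TSV, header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "target_ct", "reference_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_term_map(path: PathLike) -> pd.DataFrame:
    """Term-to-gene mapping: term_id, gene_id [, term_name, category]."""
    df = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise ParseError(f"{path}: need term_id and gene_id columns")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    if "category" not in df.columns:
        df["category"] = "default"
    return df
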