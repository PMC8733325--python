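"""Descriptive characterisation of peaks and reads.

Genomic-region assignment (5'UTR/CDS/3'UTR/exon/intron/intergenic),
RNA-biotype peak counts, cross-sample peak overlap (Venn-style
summary), RPKM expression and hierarchically clustered Pearson
correlation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .intervals import AlignedRead, GeneModel, GenomicInterval, Peak
from .peak_calling import assign_reads_to_genes

__all__ = [
    "REGION_LABELS",
    "OverlapSummary",
    "assign_region",
    "region_distribution",
    "biotype_peak_counts",
    "peak_overlap",
    "compute_rpkm",
    "sample_correlation",
]

#: region labels; the tuple order is also the tie-break precedence
REGION_LABELS = ("CDS", "3'UTR", "5'UTR", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class OverlapSummary:
    """Two-set interval overlap counts, reported from both sides.

    Interval overlap is not one-to-one, so the intersection size
    differs depending on the side it is counted from; both are kept.
    """

    n_a_only: int
    n_b_only: int
    n_overlapping_pairs: int
    a_with_overlap: int
    b_with_overlap: int


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def _gene_category_intervals(gene: GeneModel) -> list[tuple[str, GenomicInterval]]:
    """Per-category sub-intervals of a gene.

    mRNA exonic bases split into 5'UTR / CDS / 3'UTR (strand-aware);
    non-coding exonic bases are 'exon'; intra-span gaps are 'intron'.
    """
    cats: list[tuple[str, GenomicInterval]] = []
    cats.extend(("intron", iv) for iv in gene.introns())
    if gene.biotype == "mRNA" and gene.cds:
        cds = list(gene.cds)
        cds_lo = min(c.start for c in cds)
        cds_hi = max(c.end for c in cds)
        cats.extend(("CDS", c) for c in cds)
        left_label = "5'UTR" if gene.interval.strand != "-" else "3'UTR"
        right_label = "3'UTR" if gene.interval.strand != "-" else "5'UTR"
        for e in gene.exons:
            if e.start < cds_lo:
                cats.append(
                    (left_label,
                     GenomicInterval(e.chrom, e.start, min(e.end, cds_lo),
                                     e.strand))
                )
            if e.end > cds_hi:
                cats.append(
                    (right_label,
                     GenomicInterval(e.chrom, max(e.start, cds_hi), e.end,
                                     e.strand))
                )
    else:
        cats.extend(("exon", e) for e in gene.exons)
    return cats


def assign_region(
    item: GenomicInterval,
    genes: Sequence[GeneModel],
    *,
    precedence: Sequence[str] = REGION_LABELS,
) -> str:
    """Label an interval by the base-majority category of overlapped gene bases.

    No gene overlap -> 'intergenic'.  Overlapping bases are counted per
    category across all overlapping genes; exact base-count ties break
    by the configured precedence (default CDS > 3'UTR > 5'UTR > exon >
    intron).
    """
    counts: dict[str, int] = {}
    for gene in genes:
        if not item.overlaps(gene.interval):
            continue
        for cat, iv in _gene_category_intervals(gene):
            ov = item.overlap_length(iv)
            if ov:
                counts[cat] = counts.get(cat, 0) + ov
    if not counts:
        return "intergenic"
    rank = {label: i for i, label in enumerate(precedence)}
    return max(counts, key=lambda c: (counts[c], -rank[c]))


def region_distribution(
    items: Sequence[GenomicInterval] | Sequence[AlignedRead] | Sequence[Peak],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Count items per region label; fractions sum to 1 over non-empty input."""
    ivs = [getattr(x, "interval", x) for x in items]
    if not ivs:
        return pd.DataFrame(columns=["region", "count", "fraction"])
    # one tree pass to shortlist candidate genes per item
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, i
        )
    labels = []
    for iv in ivs:
        tree = trees.get(iv.chrom)
        cands = [genes[h.data] for h in tree[iv.start:iv.end]] if tree else []
        labels.append(assign_region(iv, cands))
    counts = pd.Series(labels).value_counts()
    df = pd.DataFrame(
        {
            "region": list(REGION_LABELS),
            "count": [int(counts.get(r, 0)) for r in REGION_LABELS],
        }
    )
    df = df[df["count"] > 0].reset_index(drop=True)
    df["fraction"] = df["count"] / df["count"].sum()
    return df


def biotype_peak_counts(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Peak counts per RNA biotype (plus intergenic); counts sum to |peaks|."""
    biotype_of = {g.gene_id: g.biotype for g in genes}
    order = ("mRNA", "lncRNA", "other_ncRNA", "intergenic")
    counts = dict.fromkeys(order, 0)
    for p in peaks:
        counts[biotype_of.get(p.gene_id, "intergenic")] += 1
    return pd.DataFrame({"biotype": list(order),
                         "peak_count": [counts[b] for b in order]})


# ---------------------------------------------------------------------------
# cross-sample overlap
# ---------------------------------------------------------------------------

def peak_overlap(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> OverlapSummary:
    """Venn-style overlap summary between two peak sets (>= 1 shared bp)."""
    tree_b: dict[str, IntervalTree] = {}
    for j, p in enumerate(peaks_b):
        tree_b.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, j
        )
    a_hit = 0
    b_hit_idx: set[int] = set()
    pairs = 0
    for p in peaks_a:
        tree = tree_b.get(p.interval.chrom)
        hits = tree[p.interval.start:p.interval.end] if tree else ()
        if hits:
            a_hit += 1
            pairs += len(hits)
            b_hit_idx.update(h.data for h in hits)
    return OverlapSummary(
        n_a_only=len(peaks_a) - a_hit,
        n_b_only=len(peaks_b) - len(b_hit_idx),
        n_overlapping_pairs=pairs,
        a_with_overlap=a_hit,
        b_with_overlap=len(b_hit_idx),
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def compute_rpkm(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel],
    *,
    length_mode: str = "span",
    library_size: int | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads.

    ``rpkm = read_count / ((gene_length/1e3) * (library_size/1e6))``
    with library_size defaulting to the total reads in the sample.
    Reads are counted for the gene they overlap most; ``length_mode``
    chooses the gene span (default) or the exon-union length.
    """
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("zero library size")
    if length_mode not in ("span", "exon_union"):
        raise ValueError(f"unknown length_mode {length_mode!r}")
    assigned, _ = assign_reads_to_genes(reads, genes)
    rows = []
    for g in genes:
        n = len(assigned.get(g.gene_id, ()))
        length = g.span_length if length_mode == "span" else g.exon_union_length
        rpkm = n / ((length / 1e3) * (library_size / 1e6))
        rows.append({"gene_id": g.gene_id, "read_count": n,
                     "gene_length": length, "rpkm": rpkm})
    return pd.DataFrame(rows)


def sample_correlation(
    expr_tables: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of log2(RPKM+1) between samples, clustered.

    Gene universes are outer-joined (missing -> 0).  Returns the
    symmetric unit-diagonal correlation matrix and the leaf order of an
    average-linkage hierarchical clustering on the (1 - r) distance.
    """
    if len(expr_tables) < 2:
        raise ValueError("need >= 2 samples")
    mat = pd.DataFrame(
        {name: tbl.set_index("gene_id")["rpkm"]
         for name, tbl in expr_tables.items()}
    ).fillna(0.0)
    logm = np.log2(mat + 1.0)
    for name in logm.columns:
        if logm[name].std(ddof=0) == 0:
            raise ValueError(f"sample {name!r} has constant expression; "
                             "correlation undefined")
    corr = logm.corr(method="pearson")
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    z = linkage(dist, method="average")
    order = [corr.columns[i] for i in leaves_list(z)]
    return corr, order
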