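"""Permutation-null peak calling on protein-bound RNA reads.

The procedure, per gene:

1. Reads with at least 1 bp mutual overlap are clustered into peaks;
   a peak's *height* is the maximum per-base read coverage inside it.
2. A null distribution of maximum peak heights is built by repeatedly
   (default 500 times) re-placing the same number of reads, with the
   same lengths, uniformly at random within the gene, re-clustering,
   and recording the maximum height of each placement.
3. Each observed peak receives the empirical p-value
   ``p = #{null max height >= observed height} / n_simulations`` and is
   selected when ``p < alpha`` (strict, default 0.05).

IP and input samples are processed independently; selected IP peaks
that share >= 1 bp with a selected input peak are then removed
(:func:`subtract_input`).

Reads overlapping no gene are clustered into intergenic peaks for
descriptive statistics but receive no p-value and are never selected,
because the null model is defined per gene.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import AlignedRead, GeneModel, GenomicInterval, Peak

__all__ = [
    "PeakCallingConfig",
    "cluster_reads",
    "simulate_null_max_heights",
    "empirical_pvalue",
    "assign_reads_to_genes",
    "call_peaks",
    "subtract_input",
]


@dataclass
class PeakCallingConfig:
    """Knobs of the permutation peak caller.

    n_simulations : random read placements per gene (default 500).
    alpha : selection threshold on the empirical p (strict <, default 0.05).
    min_reads_per_peak : peaks with fewer constituent reads are never selected.
    seed : master seed; per-gene streams are derived from it so results
        do not depend on gene iteration order.
    stranded : when True, reads are clustered and assigned per strand
        ('.' matches either strand during gene assignment).
    null_placement : 'span' places null reads uniformly over the gene
        span (introns included, the default); 'exon_union' restricts
        placement to exonic coordinates.
    smooth_pvalues : use (k+1)/(N+1) instead of k/N.
    """

    n_simulations: int = 500
    alpha: float = 0.05
    min_reads_per_peak: int = 1
    seed: int = 0
    stranded: bool = False
    null_placement: str = "span"
    smooth_pvalues: bool = False

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.null_placement not in ("span", "exon_union"):
            raise ValueError(f"unknown null_placement {self.null_placement!r}")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _max_coverage(starts: np.ndarray, ends: np.ndarray) -> int:
    """Maximum per-base coverage of half-open intervals (event sweep)."""
    if starts.size == 0:
        return 0
    # encode position*2 + is_start so that an end sorts before a start at
    # the same coordinate: [a, p) and [p, b) must not count as overlapping
    keys = np.concatenate((starts * 2 + 1, ends * 2))
    deltas = np.concatenate((np.ones(starts.size, dtype=np.int64),
                             -np.ones(ends.size, dtype=np.int64)))
    order = np.argsort(keys, kind="stable")
    return int(np.cumsum(deltas[order]).max())


def cluster_reads(
    reads: Sequence[AlignedRead], *, stranded: bool = False
) -> list[Peak]:
    """Cluster reads into peaks by transitive >=1 bp overlap.

    Returns peaks ordered by (chrom, start) with height and read_count
    filled and ``p_value`` undefined.  With ``stranded=True`` reads are
    grouped by strand before clustering.
    """
    if not reads:
        return []
    groups: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        key = (r.interval.chrom, r.interval.strand if stranded else ".")
        groups.setdefault(key, []).append(r)

    peaks: list[Peak] = []
    for (chrom, _strand_key) in sorted(groups):
        members = sorted(groups[(chrom, _strand_key)],
                         key=lambda r: (r.interval.start, r.interval.end))
        cluster: list[AlignedRead] = []
        cluster_end = -1
        for r in members + [None]:  # sentinel flushes the last cluster
            if r is not None and (not cluster or r.interval.start < cluster_end):
                cluster.append(r)
                cluster_end = max(cluster_end, r.interval.end)
                continue
            if cluster:
                starts = np.array([m.interval.start for m in cluster])
                ends = np.array([m.interval.end for m in cluster])
                strands = {m.interval.strand for m in cluster}
                peaks.append(
                    Peak(
                        GenomicInterval(
                            chrom, int(starts.min()), int(ends.max()),
                            strands.pop() if len(strands) == 1 else ".",
                        ),
                        peak_id=f"peak_{len(peaks)}",
                        height=_max_coverage(starts, ends),
                        read_count=len(cluster),
                    )
                )
            if r is not None:
                cluster = [r]
                cluster_end = r.interval.end
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    for i, p in enumerate(peaks):
        p.peak_id = f"peak_{i + 1}"
    return peaks


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _null_max_heights_on_span(
    span_length: int,
    read_lengths: np.ndarray,
    n_simulations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised random placement on a contiguous [0, span) axis."""
    n_reads = read_lengths.size
    if n_reads == 0:
        return np.zeros(n_simulations, dtype=np.int64)
    high = np.maximum(span_length - read_lengths, 0) + 1  # valid starts per read
    starts = rng.integers(0, high, size=(n_simulations, n_reads))
    ends = np.minimum(starts + read_lengths, span_length)
    # per-row event sweep: ends (key 2p) sort before starts (key 2p+1)
    keys = np.concatenate((starts * 2 + 1, ends * 2), axis=1)
    deltas = np.concatenate(
        (np.ones_like(starts), -np.ones_like(ends)), axis=1
    )
    order = np.argsort(keys, axis=1, kind="stable")
    swept = np.take_along_axis(deltas, order, axis=1)
    return np.cumsum(swept, axis=1).max(axis=1)


def simulate_null_max_heights(
    gene: GeneModel,
    read_lengths: Sequence[int],
    n_simulations: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    *,
    placement: str = "span",
) -> np.ndarray:
    """Null distribution of per-placement maximum peak heights for a gene.

    Each of ``n_simulations`` placements drops ``len(read_lengths)``
    reads, with the given lengths, uniformly at random within the gene
    (start drawn uniformly among positions keeping the read inside),
    clusters them, and records the maximum peak height (0 when no
    reads).  ``placement='exon_union'`` uses the concatenated exonic
    axis instead of the genomic span.
    """
    lengths = np.asarray(read_lengths, dtype=np.int64)
    if placement == "span":
        axis_length = gene.span_length
    elif placement == "exon_union":
        axis_length = gene.exon_union_length
    else:
        raise ValueError(f"unknown placement {placement!r}")
    if lengths.size and lengths.max() > axis_length:
        raise ValueError(
            f"gene {gene.gene_id}: read length {int(lengths.max())} exceeds "
            f"{placement} length {axis_length}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return _null_max_heights_on_span(axis_length, lengths, n_simulations, rng)


def empirical_pvalue(
    observed_height: int,
    null_max_heights: Sequence[int] | np.ndarray,
    *,
    smooth: bool = False,
) -> float:
    """Fraction of null placements whose max height reaches the observed one.

    ``p = #{null >= observed} / N``; with ``smooth=True`` the +1/(N+1)
    estimator is used instead.
    """
    null = np.asarray(null_max_heights)
    if null.size == 0:
        raise ValueError("empty null distribution")
    k = int((null >= observed_height).sum())
    if smooth:
        return (k + 1) / (null.size + 1)
    return k / null.size


# ---------------------------------------------------------------------------
# gene assignment and the full procedure
# ---------------------------------------------------------------------------

def assign_reads_to_genes(
    reads: Iterable[AlignedRead],
    genes: Sequence[GeneModel],
    *,
    stranded: bool = False,
) -> tuple[dict[str, list[AlignedRead]], list[AlignedRead]]:
    """Assign each read to the gene it overlaps most.

    A read overlapping two genes goes to the one with the larger
    overlap; exact ties go to the lexicographically smaller gene_id.
    Returns (per-gene reads, intergenic reads).
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g.gene_id
        )
    assigned: dict[str, list[AlignedRead]] = {}
    intergenic: list[AlignedRead] = []
    for r in reads:
        tree = trees.get(r.interval.chrom)
        hits = tree[r.interval.start:r.interval.end] if tree else ()
        best: Optional[str] = None
        best_ov = 0
        for hit in hits:
            g = by_id[hit.data]
            if stranded and not r.interval.strands_compatible(g.interval):
                continue
            ov = r.interval.overlap_length(g.interval)
            if ov > best_ov or (ov == best_ov and best is not None
                                and hit.data < best):
                best, best_ov = hit.data, ov
        if best is None:
            intergenic.append(r)
        else:
            assigned.setdefault(best, []).append(r)
    return assigned, intergenic


def _gene_seed(master_seed: int, gene_id: str) -> np.random.SeedSequence:
    # stable per-gene stream independent of iteration order
    return np.random.SeedSequence([master_seed, zlib.crc32(gene_id.encode())])


def call_peaks(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel],
    config: PeakCallingConfig | None = None,
) -> list[Peak]:
    """Run the whole permutation peak-calling procedure on one sample.

    Reads are assigned to genes by largest overlap; per gene, reads are
    clustered, one shared null of maximum peak heights is simulated
    from all that gene's reads, and each peak is tested against it.
    Intergenic clusters are reported with ``p_value=None`` and never
    selected.  Deterministic given ``config.seed``.
    """
    config = config or PeakCallingConfig()
    assigned, intergenic = assign_reads_to_genes(
        reads, genes, stranded=config.stranded
    )
    by_id = {g.gene_id: g for g in genes}
    all_peaks: list[Peak] = []

    for gene_id in sorted(assigned):
        gene = by_id[gene_id]
        gene_reads = assigned[gene_id]
        peaks = cluster_reads(gene_reads, stranded=config.stranded)
        # reads are placed within the gene axis, so a read overhanging the
        # gene boundary contributes its truncated length to the null
        axis = (gene.span_length if config.null_placement == "span"
                else gene.exon_union_length)
        lengths = [min(r.interval.length, axis) for r in gene_reads]
        null = simulate_null_max_heights(
            gene, lengths, config.n_simulations,
            _gene_seed(config.seed, gene_id),
            placement=config.null_placement,
        )
        for p in peaks:
            p.gene_id = gene_id
            p.p_value = empirical_pvalue(
                p.height, null, smooth=config.smooth_pvalues
            )
            p.selected = (p.p_value < config.alpha
                          and p.read_count >= config.min_reads_per_peak)
        all_peaks.extend(peaks)

    for p in cluster_reads(intergenic, stranded=config.stranded):
        p.gene_id = "intergenic"
        p.p_value = None
        p.selected = False
        all_peaks.append(p)

    all_peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start,
                                  p.interval.end))
    for i, p in enumerate(all_peaks):
        p.peak_id = f"peak_{i + 1:05d}"
    return all_peaks


def subtract_input(
    ip_peaks: Sequence[Peak],
    input_peaks: Sequence[Peak],
    *,
    stranded: bool = False,
) -> list[Peak]:
    """Remove IP peaks sharing >= 1 bp with any input peak.

    Half-open semantics: adjacency ([100,200) vs [200,300)) is not
    overlap.  The result is always a subset of ``ip_peaks``.
    """
    trees: dict[str, IntervalTree] = {}
    for p in input_peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p.interval.strand
        )
    kept: list[Peak] = []
    for p in ip_peaks:
        tree = trees.get(p.interval.chrom)
        hits = tree[p.interval.start:p.interval.end] if tree else ()
        if stranded:
            iv = p.interval
            hits = [h for h in hits
                    if iv.strand == "." or h.data == "." or h.data == iv.strand]
        if not hits:
            kept.append(p)
    return kept
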