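"""Synthetic RIP-seq data with planted ground truth.

The generator emulates the statistical structure the peak caller
assumes: genes of varying length and biotype laid out with intergenic
gaps on a synthetic chromosome; input-sample reads placed uniformly
over gene spans (plus an intergenic fraction); IP-sample reads drawn
from a mixture that concentrates a tunable fold of density on planted
binding sites; fixed read length (150 bp, truncated at gene ends); and
site sequences carrying an embedded 5-mer motif (GGGAU by default) in
a tunable fraction of the foreground.

Start positions of IP reads are drawn from a piecewise-constant
density: weight ``ip_enrichment`` on start positions whose read would
overlap a planted site, weight 1 elsewhere.  With ``ip_enrichment=1``
this reduces exactly to the uniform placement used for the input
sample — the no-signal case is the caller's null by construction.

Everything is deterministic given ``SimulationConfig.seed``: the same
config yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import AlignedRead, GeneModel, GenomicInterval

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_annotation",
    "plant_sites",
    "simulate_reads",
    "emit_site_sequences",
    "emit_genome",
    "make_ct_table",
]

RNA_ALPHABET = "ACGU"

#: minimum exon / intron piece when splitting a gene into exons
_MIN_SEGMENT = 50


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults describe a desk-scale experiment: 100 genes of 2-10 kb on
    one chromosome, ~100 reads per gene and sample, one 200 bp binding
    site per gene at 8-fold IP enrichment, 150 bp reads, and a GGGAU
    motif planted in 40% of site sequences.
    """

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    lncRNA_fraction: float = 0.3
    read_length: int = 150
    background_reads_per_gene: float = 100.0
    n_sites_per_gene: int = 1
    site_width: int = 200
    ip_enrichment: float = 8.0
    intergenic_read_fraction: float = 0.1
    motif: str = "GGGAU"
    motif_plant_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        for name in ("lncRNA_fraction", "intergenic_read_fraction",
                     "motif_plant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ip_enrichment < 1.0:
            raise ValueError("ip_enrichment must be >= 1")
        if self.n_genes and self.site_width >= lo:
            raise ValueError("site_width must be smaller than the shortest gene")
        if set(self.motif) - set(RNA_ALPHABET):
            raise ValueError("motif must use the RNA alphabet ACGU")


@dataclass
class GroundTruth:
    """Planted truth: binding sites per gene and motif plant positions."""

    sites: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    motif_positions: list[tuple[str, int]] = field(default_factory=list)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, order-stable stream per generator stage
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _split_exons(
    span: GenomicInterval, rng: np.random.Generator
) -> tuple[GenomicInterval, ...]:
    """Cut a gene span into 1-5 exons separated by introns."""
    max_exons = max(1, min(5, span.length // (3 * _MIN_SEGMENT)))
    n_exons = int(rng.integers(1, max_exons + 1))
    if n_exons == 1:
        return (span,)
    n_seg = 2 * n_exons - 1  # exon, intron, exon, ...
    props = rng.dirichlet(np.ones(n_seg))
    spare = span.length - n_seg * _MIN_SEGMENT
    lens = (_MIN_SEGMENT + np.floor(props * spare)).astype(int)
    lens[-1] += span.length - lens.sum()
    bounds = span.start + np.concatenate(([0], np.cumsum(lens)))
    return tuple(
        GenomicInterval(span.chrom, int(bounds[i]), int(bounds[i + 1]), span.strand)
        for i in range(0, n_seg, 2)
    )


def _make_cds(
    exons: Sequence[GenomicInterval], strand: str
) -> tuple[GenomicInterval, ...]:
    """CDS = middle 70% of exonic bases; the flanks become the UTRs.

    The 5' UTR sits at the transcription start (left on '+', right on
    '-'); the split is in transcript coordinates, so a CDS may span
    several exons.
    """
    total = sum(e.length for e in exons)
    utr5 = max(1, int(round(0.15 * total)))
    utr3 = max(1, int(round(0.15 * total)))
    if utr5 + utr3 >= total:  # tiny gene: no room, keep it all CDS
        return tuple(exons)
    left_trim = utr5 if strand != "-" else utr3
    right_trim = utr3 if strand != "-" else utr5
    lo, hi = left_trim, total - right_trim  # CDS range on the exonic axis
    cds = []
    offset = 0
    for e in exons:
        a, b = max(lo, offset), min(hi, offset + e.length)
        if a < b:
            cds.append(
                GenomicInterval(e.chrom, e.start + (a - offset),
                                e.start + (b - offset), e.strand)
            )
        offset += e.length
    return tuple(cds)


def make_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping genes with intergenic gaps on one chromosome.

    Returns the gene models and a chromosome-size table.  Biotypes are
    Bernoulli(lncRNA_fraction) lncRNA, else mRNA (mRNAs get a CDS and
    UTRs); deterministic given the config seed.
    """
    rng = _rng(config, "annotation")
    genes: list[GeneModel] = []
    lo, hi = config.gene_length_range
    cursor = int(rng.integers(500, 3_000))
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval("chr1", cursor, cursor + length, strand)
        is_lnc = rng.random() < config.lncRNA_fraction
        exons = _split_exons(span, rng)
        if is_lnc:
            gene = GeneModel(f"gene_{i + 1:04d}", span, "lncRNA", exons)
        else:
            gene = GeneModel(f"gene_{i + 1:04d}", span, "mRNA", exons,
                             _make_cds(exons, strand))
        genes.append(gene)
        cursor = span.end + int(rng.integers(500, 3_000))
    chrom_sizes = {"chr1": cursor + 500} if config.n_genes else {"chr1": 10_000}
    return genes, chrom_sizes


def plant_sites(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> list[tuple[str, GenomicInterval]]:
    """Plant ``n_sites_per_gene`` non-overlapping sites inside each gene span."""
    rng = _rng(config, "sites")
    sites: list[tuple[str, GenomicInterval]] = []
    w = config.site_width
    for g in genes:
        placed: list[GenomicInterval] = []
        attempts = 0
        while len(placed) < config.n_sites_per_gene:
            attempts += 1
            if attempts > 1000:
                raise ValueError(
                    f"cannot place {config.n_sites_per_gene} sites of {w} bp "
                    f"in gene {g.gene_id} ({g.span_length} bp)"
                )
            start = int(rng.integers(g.interval.start, g.interval.end - w + 1))
            cand = GenomicInterval(g.interval.chrom, start, start + w,
                                   g.interval.strand)
            if all(not cand.overlaps(p) for p in placed):
                placed.append(cand)
        placed.sort(key=lambda iv: iv.start)
        sites.extend((g.gene_id, iv) for iv in placed)
    return sites


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _site_start_windows(
    gene: GeneModel, sites: Sequence[GenomicInterval], read_length: int
) -> list[tuple[int, int]]:
    """Start-position windows [a, b) in which a read overlaps a site."""
    g = gene.interval
    start_lo = g.start
    start_hi = g.end - min(read_length, g.length) + 1  # exclusive
    windows = []
    for s in sites:
        a = max(start_lo, s.start - read_length + 1)
        b = min(start_hi, s.end)
        if a < b:
            windows.append((a, b))
    return windows


def _sample_gene_starts(
    gene: GeneModel,
    sites: Sequence[GenomicInterval],
    n_reads: int,
    read_length: int,
    enrichment: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw read starts from the piecewise-constant site-enriched density."""
    g = gene.interval
    eff_len = min(read_length, g.length)
    lo, hi = g.start, g.end - eff_len + 1
    if enrichment == 1.0 or not sites:
        return rng.integers(lo, hi, size=n_reads)
    windows = _site_start_windows(gene, sites, read_length)
    # windows may touch; merge to keep the complement well defined
    merged: list[list[int]] = []
    for a, b in sorted(windows):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    w_len = sum(b - a for a, b in merged)
    n_valid = hi - lo
    total_weight = n_valid + (enrichment - 1.0) * w_len
    p_site = enrichment * w_len / total_weight
    in_site = rng.random(n_reads) < p_site
    starts = np.empty(n_reads, dtype=np.int64)
    # site draws: uniform over the merged windows
    n_site = int(in_site.sum())
    if n_site:
        lens = np.array([b - a for a, b in merged])
        which = rng.choice(len(merged), size=n_site, p=lens / lens.sum())
        offs = rng.integers(0, lens[which])
        starts[in_site] = np.array([merged[i][0] for i in which]) + offs
    # background draws: uniform over the complement segments
    n_bg = n_reads - n_site
    if n_bg:
        segs = []
        cur = lo
        for a, b in merged:
            if a > cur:
                segs.append((cur, a))
            cur = b
        if cur < hi:
            segs.append((cur, hi))
        lens = np.array([b - a for a, b in segs])
        which = rng.choice(len(segs), size=n_bg, p=lens / lens.sum())
        offs = rng.integers(0, lens[which])
        starts[~in_site] = np.array([segs[i][0] for i in which]) + offs
    return starts


def _intergenic_gaps(
    genes: Sequence[GeneModel], chrom_sizes: dict[str, int]
) -> list[GenomicInterval]:
    gaps: list[GenomicInterval] = []
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, size in chrom_sizes.items():
        cur = 0
        for g in sorted(per_chrom.get(chrom, []), key=lambda g: g.interval.start):
            if g.interval.start > cur:
                gaps.append(GenomicInterval(chrom, cur, g.interval.start))
            cur = max(cur, g.interval.end)
        if cur < size:
            gaps.append(GenomicInterval(chrom, cur, size))
    return gaps


def simulate_reads(
    genes: Sequence[GeneModel],
    truth_sites: Sequence[tuple[str, GenomicInterval]],
    config: SimulationConfig,
    chrom_sizes: Optional[dict[str, int]] = None,
    *,
    sample_ip: str = "IP",
    sample_input: str = "Input",
) -> tuple[list[AlignedRead], list[AlignedRead], GroundTruth]:
    """Simulate one IP and one matched input sample.

    Per gene, read counts are Poisson(background_reads_per_gene) in
    both samples; input starts are uniform over the span, IP starts
    follow the site-enriched density.  An intergenic read pool sized so
    that intergenic reads make up ``intergenic_read_fraction`` of each
    sample (in expectation) is placed uniformly in the gaps between
    genes.  Reads are truncated at gene/gap ends; deterministic given
    the config seed.
    """
    sites_by_gene: dict[str, list[GenomicInterval]] = {}
    for gene_id, iv in truth_sites:
        sites_by_gene.setdefault(gene_id, []).append(iv)
    by_id = {g.gene_id: g for g in genes}
    for gene_id, ivs in sites_by_gene.items():
        g = by_id[gene_id]
        for iv in ivs:
            if iv.start < g.interval.start or iv.end > g.interval.end:
                raise ValueError(f"site {iv} outside gene {gene_id}")
            if iv.length > g.span_length:
                raise ValueError(f"site wider than gene {gene_id}")

    L = config.read_length
    out: dict[str, list[AlignedRead]] = {sample_ip: [], sample_input: []}
    for sample, enriched in ((sample_ip, True), (sample_input, False)):
        rng = _rng(config, f"reads:{sample}")
        counter = 0
        for g in sorted(genes, key=lambda g: g.gene_id):
            n = int(rng.poisson(config.background_reads_per_gene))
            if n == 0:
                continue
            enr = config.ip_enrichment if enriched else 1.0
            starts = _sample_gene_starts(
                g, sites_by_gene.get(g.gene_id, ()), n, L, enr, rng
            )
            eff = min(L, g.span_length)
            for s in starts:
                counter += 1
                end = min(int(s) + eff, g.interval.end)
                out[sample].append(
                    AlignedRead(
                        GenomicInterval(g.interval.chrom, int(s), end,
                                        g.interval.strand),
                        f"{sample}_r{counter:07d}", sample,
                    )
                )
        # intergenic background
        f = config.intergenic_read_fraction
        if f > 0 and genes:
            gaps = [gap for gap in
                    _intergenic_gaps(genes, chrom_sizes or {})
                    if gap.length > L]
            if gaps:
                n_genic = counter
                n_inter = int(rng.poisson(f / (1.0 - f) * n_genic)) if f < 1 \
                    else int(rng.poisson(config.background_reads_per_gene))
                lens = np.array([gap.length - L for gap in gaps])
                which = rng.choice(len(gaps), size=n_inter, p=lens / lens.sum())
                offs = rng.integers(0, lens[which])
                for i, o in zip(which, offs):
                    counter += 1
                    s = gaps[i].start + int(o)
                    out[sample].append(
                        AlignedRead(
                            GenomicInterval(gaps[i].chrom, s, s + L, "."),
                            f"{sample}_r{counter:07d}", sample,
                        )
                    )
    truth = GroundTruth(sites=list(truth_sites))
    return out[sample_ip], out[sample_input], truth


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(RNA_ALPHABET))[rng.integers(0, 4, size=length)])


def emit_site_sequences(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, str], dict[str, str]]:
    """Foreground (site) and matched background sequences.

    Foreground sequences are random RNA of ``site_width`` bases with
    the motif overwritten at a random offset in ``motif_plant_fraction``
    of them; plants are recorded in ``truth.motif_positions``.  The
    background is an equal number of random sequences of the same
    length with no deliberate motif.
    """
    rng = _rng(config, "sequences")
    motif = config.motif
    w = config.site_width
    if w < len(motif):
        raise ValueError("site_width shorter than the motif")
    fg: dict[str, str] = {}
    bg: dict[str, str] = {}
    truth.motif_positions = []
    for i, (gene_id, iv) in enumerate(truth.sites):
        name = f"site_{i + 1:04d}|{gene_id}"
        seq = _random_seq(rng, w)
        if rng.random() < config.motif_plant_fraction:
            off = int(rng.integers(0, w - len(motif) + 1))
            seq = seq[:off] + motif + seq[off + len(motif):]
            truth.motif_positions.append((name, off))
        fg[name] = seq
        bg[f"bg_{i + 1:04d}"] = _random_seq(rng, w)
    return fg, bg


def emit_genome(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, str]:
    """Random DNA genome with the motif planted at site centres.

    The motif is written in plus-strand DNA orientation (U -> T) at the
    centre of ``motif_plant_fraction`` of the planted sites, so that
    unstranded peak-sequence extraction recovers it directly.
    """
    rng = _rng(config, "genome")
    motif_dna = config.motif.replace("U", "T")
    chroms = {
        chrom: np.array(list("ACGT"))[rng.integers(0, 4, size=size)]
        for chrom, size in chrom_sizes.items()
    }
    for _gene_id, iv in truth.sites:
        if rng.random() < config.motif_plant_fraction:
            mid = (iv.start + iv.end - len(motif_dna)) // 2
            chroms[iv.chrom][mid:mid + len(motif_dna)] = list(motif_dna)
    return {chrom: "".join(arr) for chrom, arr in chroms.items()}


# ---------------------------------------------------------------------------
# Ct table
# ---------------------------------------------------------------------------

def make_ct_table(
    n_per_group: int,
    true_fold_change: float,
    seed: int = 0,
    *,
    noise_sd: float = 0.15,
    reference_ct: float = 18.0,
    control_delta_ct: float = 3.0,
    group_labels: tuple[str, str] = ("control", "remodeling"),
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for two groups.

    The reference gene sits at ``reference_ct`` + noise in every
    sample; the target sits ``control_delta_ct`` cycles above it in the
    control group and is shifted by ``-log2(true_fold_change)`` cycles
    in the second group, so the 2^-ddCt estimate recovers
    ``true_fold_change`` (exactly when ``noise_sd=0``).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    control, treated = group_labels
    for group in (control, treated):
        shift = 0.0 if group == control else -np.log2(true_fold_change)
        for i in range(n_per_group):
            ref = reference_ct + rng.normal(0.0, noise_sd)
            tgt = (reference_ct + control_delta_ct + shift
                   + rng.normal(0.0, noise_sd))
            rows.append(
                {"sample_id": f"{group}_{i + 1}", "group": group,
                 "target_ct": tgt, "reference_ct": ref}
            )
    return pd.DataFrame(rows)
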