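"""Exhaustive k-mer enrichment in peak sequences versus background.

A streamlined motif scan: every k-mer observed in the sequences is
scored by presence/absence counts (how many foreground and background
sequences contain it at least once), a hypergeometric upper-tail
p-value on the resulting 2x2 occurrence table, and a fold enrichment.
Results are ranked by p ascending, ties by fold descending then
lexicographic.  When no background is supplied, a seeded per-sequence
dinucleotide shuffle of the foreground is used, preserving each
sequence's dinucleotide composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .enrichment import hypergeom_upper_tail
from .intervals import Peak

__all__ = [
    "KmerResult",
    "extract_peak_sequences",
    "kmer_enrichment",
    "top_motifs",
    "dinucleotide_shuffle",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


@dataclass(frozen=True)
class KmerResult:
    """One k-mer with its occurrence counts, enrichment and rank."""

    kmer: str
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    fold: float
    p_value: float
    rank: int = 0


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_peak_sequences(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    *,
    stranded: bool = False,
    rna: bool = True,
) -> dict[str, str]:
    """Slice each peak's sequence out of the genome.

    Minus-strand peaks are reverse-complemented when ``stranded``;
    ``rna=True`` reports sequences in the RNA alphabet (T -> U).
    """
    out: dict[str, str] = {}
    for p in peaks:
        iv = p.interval
        if iv.chrom not in genome:
            raise ValueError(f"{p.peak_id}: unknown chromosome {iv.chrom}")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"{p.peak_id}: peak end {iv.end} beyond chromosome "
                f"{iv.chrom} length {len(chrom_seq)}"
            )
        seq = chrom_seq[iv.start:iv.end].upper()
        if stranded and iv.strand == "-":
            seq = _revcomp(seq)
        if rna:
            seq = seq.replace("T", "U")
        out[p.peak_id] = seq
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erikson style: build the multigraph of dinucleotide
    transitions, draw a random Eulerian walk from the original start
    vertex by shuffling each vertex's outgoing edges (keeping a
    spanning arborescence to the end vertex so the walk completes).
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick, for every vertex except the terminal one, a final outgoing
    # edge lying on a path to the terminal vertex (Altschul-Erikson)
    vertices = list(edges)
    final_edge: dict[str, str] = {}
    while True:
        for v in vertices:
            if v != last:
                final_edge[v] = str(rng.choice(edges[v]))
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last and cur in final_edge:
                cur = final_edge[cur]
                if cur in seen:
                    break
                seen.add(cur)
            if cur != last:
                ok = False
                break
        if ok:
            break
    remaining = {
        v: [e for e in out_edges] for v, out_edges in edges.items()
    }
    for v, e in final_edge.items():
        remaining[v].remove(e)
    for v in remaining:
        rng.shuffle(remaining[v])
        if v in final_edge:
            remaining[v].append(final_edge[v])
    result = [seq[0]]
    cur = seq[0]
    counters = {v: 0 for v in remaining}
    while counters[cur] < len(remaining[cur]):
        nxt = remaining[cur][counters[cur]]
        counters[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def _kmer_presence(sequences: Sequence[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in sequences:
        seen = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _kmer_occurrences(sequences: Sequence[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(
    fg: Sequence[str] | Mapping[str, str],
    bg: Optional[Sequence[str] | Mapping[str, str]] = None,
    k: int = 5,
    *,
    mode: str = "presence",
    seed: int = 0,
) -> list[KmerResult]:
    """Rank all observed k-mers by foreground-vs-background enrichment.

    Counting is presence/absence per sequence by default
    (``mode='occurrences'`` counts every hit).  The p-value is the
    hypergeometric upper tail of drawing ``fg_total`` sequences from
    the pooled ``fg_total + bg_total`` with ``fg_with + bg_with``
    carriers.  Fold is the ratio of carrier rates, with a 0.5-count
    continuity correction when ``bg_with = 0``.  With ``bg=None`` a
    seeded dinucleotide shuffle of the foreground is used.
    """
    fg_seqs = list(fg.values()) if isinstance(fg, Mapping) else list(fg)
    if not fg_seqs:
        raise ValueError("empty foreground")
    if not (1 <= k <= min(len(s) for s in fg_seqs)):
        raise ValueError("k exceeds the shortest foreground sequence")
    if bg is None:
        rng = np.random.default_rng(seed)
        bg_seqs = [dinucleotide_shuffle(s, rng) for s in fg_seqs]
    else:
        bg_seqs = list(bg.values()) if isinstance(bg, Mapping) else list(bg)
    if not bg_seqs:
        raise ValueError("empty background")
    if k > min(len(s) for s in bg_seqs):
        raise ValueError("k exceeds the shortest background sequence")

    counter = _kmer_presence if mode == "presence" else _kmer_occurrences
    if mode not in ("presence", "occurrences"):
        raise ValueError(f"unknown mode {mode!r}")
    fg_counts = counter(fg_seqs, k)
    bg_counts = counter(bg_seqs, k)
    fg_total = (len(fg_seqs) if mode == "presence"
                else sum(len(s) - k + 1 for s in fg_seqs))
    bg_total = (len(bg_seqs) if mode == "presence"
                else sum(len(s) - k + 1 for s in bg_seqs))

    results = []
    for kmer in sorted(set(fg_counts) | set(bg_counts)):
        fw = fg_counts.get(kmer, 0)
        bw = bg_counts.get(kmer, 0)
        if bw > 0:
            fold = (fw / fg_total) / (bw / bg_total)
        else:
            fold = (fw + 0.5) / fg_total / (0.5 / bg_total)
        p = hypergeom_upper_tail(fw, fw + bw, fg_total, fg_total + bg_total)
        results.append(
            KmerResult(kmer, fw, fg_total, bw, bg_total, fold, p)
        )
    results.sort(key=lambda r: (r.p_value, -r.fold, r.kmer))
    return [
        KmerResult(r.kmer, r.fg_with, r.fg_total, r.bg_with, r.bg_total,
                   r.fold, r.p_value, rank=i + 1)
        for i, r in enumerate(results)
    ]


def top_motifs(results: Sequence[KmerResult], n: int) -> list[KmerResult]:
    """First ``n`` ranked k-mers (all of them when n exceeds the table)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return list(results[:n])
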