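# ripcall

Peak calling and downstream analysis for RIP-seq / CLIP-style
protein–RNA interaction data, built around a permutation null, with a
synthetic-data generator that plants full ground truth.

RIP-seq pulls down an RNA-binding protein and sequences the RNAs bound
to it. The computational question is where, along each gene, the
immunoprecipitated (IP) reads pile up more than chance placement would
allow — and whether those pile-ups survive comparison with a matched
input (non-enriched) control.

## The method

**Peaks.** Reads sharing at least 1 bp of overlap are clustered
(transitively) into peaks. A peak's *height* is the maximum per-base
read coverage inside it; all coordinates are 0-based half-open, so
reads that merely touch end-to-start do not cluster.

**Permutation null.** For each gene with reads, the same number of
reads with the same lengths are re-placed uniformly at random within
the gene span and re-clustered; the maximum peak height of each
placement is recorded. With *N* = 500 placements, each observed peak
of height *h* gets the empirical p-value

```
p = #{ placements with max height ≥ h } / N
```

and is selected when p < α (default 0.05, strict). IP and input
samples are analysed independently; selected IP peaks overlapping any
selected input peak by ≥ 1 bp are removed.

**Downstream.** Genomic-region assignment (5'UTR/CDS/3'UTR/exon/
intron/intergenic by base majority), RNA-biotype peak counts,
cross-sample peak overlap, RPKM (`reads / (kb of gene · millions of
mapped reads)`) with clustered Pearson correlation, exhaustive k-mer
motif enrichment (presence/absence counts, hypergeometric upper-tail
p), gene-set over-representation (hypergeometric + Benjamini–Hochberg
FDR per category), and 2^-ΔΔCt relative qPCR quantification.

## Worked example

Simulate 100 genes with one 200 bp binding site each at 8-fold IP
enrichment (~100 reads per gene and sample), call peaks in IP and
input, subtract, and rank 5-mers in the site sequences:

```python
from ripcall.synthetic_data import (SimulationConfig, make_annotation,
                                    plant_sites, simulate_reads,
                                    emit_site_sequences)
from ripcall.peak_calling import PeakCallingConfig, call_peaks, subtract_input
from ripcall.motif import kmer_enrichment, top_motifs

cfg = SimulationConfig(n_genes=100, ip_enrichment=8.0, seed=1)
genes, chrom_sizes = make_annotation(cfg)
sites = plant_sites(genes, cfg)
ip_reads, input_reads, truth = simulate_reads(genes, sites, cfg, chrom_sizes)

pk = PeakCallingConfig(n_simulations=500, alpha=0.05, seed=1)
ip_peaks = [p for p in call_peaks(ip_reads, genes, pk) if p.selected]
input_peaks = [p for p in call_peaks(input_reads, genes, pk) if p.selected]
final = subtract_input(ip_peaks, input_peaks)
print(f"{len(ip_peaks)} selected IP peaks, {len(input_peaks)} selected "
      f"input peaks, {len(final)} after subtraction")

hit = sum(any(iv.overlaps(p.interval) for p in final) for _, iv in sites)
print(f"{hit}/{len(sites)} planted sites recovered")

fg, bg = emit_site_sequences(truth, cfg)
for r in top_motifs(kmer_enrichment(fg, bg, k=5), 3):
    print(f"{r.rank}  {r.kmer}  fold={r.fold:.2f}  p={r.p_value:.3g}")
```

prints

```
100 selected IP peaks, 0 selected input peaks, 100 after subtraction
100/100 planted sites recovered
1  GGGAU  fold=2.88  p=3.46e-06
2  CGGGU  fold=2.70  p=0.00159
3  CGCCA  fold=2.00  p=0.00452
```

Every planted site is called and survives input subtraction (the
uniform input produces no significant peaks of its own), and the
planted GGGAU motif ranks first among all 1,024 5-mers.

The same flow is available from the shell:

```bash
ripcall simulate --n-genes 100 --seed 1 -o sim/
ripcall run --gtf sim/genes.gtf --ip sim/ip.bed --input sim/input.bed \
    --fasta sim/genome.fa --ct-table sim/ct_table.tsv --seed 1 -o out/
```

which writes peak BEDs, region/biotype/RPKM/correlation tables, k-mer
tables, a ΔΔCt summary, and a `manifest.json` of SHA-256 checksums
(byte-identical across reruns with the same seed).

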