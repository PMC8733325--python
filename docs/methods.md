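# Methods

## The peak-calling model

A *peak* is a maximal set of reads connected by pairwise ≥ 1 bp
overlap (transitive closure), represented by the union span of its
reads; its *height* is the maximum per-base coverage inside the span.
Intervals are 0-based half-open throughout, so `[0,50)` and `[50,100)`
share no base and never cluster; GTF input is converted at the I/O
boundary and converted back on write.

Significance is assessed per gene by random re-placement: each of the
`n_simulations` (default 500) rounds places the gene's reads — same
count, same lengths — uniformly at random within the gene, clusters
them, and records the maximum peak height; a read's start is drawn
uniformly among the positions that keep it inside the gene, so length
is preserved exactly. The empirical p-value of an observed peak of
height *h* is the fraction of rounds whose maximum reached *h*
(`p = #{null ≥ h}/N`, no +1 smoothing by default; a smoothed
`(k+1)/(N+1)` estimator is available as a flag). Selection uses strict
`p < alpha` (default 0.05). With 500 rounds the attainable p-values
are multiples of 1/500, which makes the selection rule conservative:
the realized per-gene type-I error sits at or below alpha.

Design points that the procedure leaves open, and the choices made:

- **Null placement axis.** Reads are re-placed over the gene *span*
  (introns included), matching the observation that bound regions are
  heavily intronic; `null_placement="exon_union"` restricts placement
  to exonic coordinates instead.
- **One null per gene.** All peaks of a gene share the gene's null
  distribution of maximum heights, rather than each peak receiving its
  own; the null uses all reads assigned to the gene (every assigned
  read belongs to some peak, so "reads in peaks" equals the gene's
  reads).
- **Gene assignment.** A read overlapping two genes goes to the larger
  overlap; exact ties go to the lexicographically smaller gene id.
  Reads overlapping no gene form intergenic peaks that are reported
  for distribution statistics but get no p-value and are never
  selected, since the null model is defined per gene. A read
  overhanging its gene's boundary contributes its truncated
  (within-span) length to the null.
- **Strandedness.** Default unstranded: strand is ignored for
  clustering, assignment and subtraction, and `.` matches either
  strand when stranded mode is enabled. Library strandedness is a
  config flag because the upstream protocol does not fix it.
- **Input subtraction.** Selected IP peaks sharing ≥ 1 bp with a
  *selected* input peak are removed (the input sample is analysed by
  the identical independent procedure first).
- **Determinism.** Each gene's null is seeded by
  `SeedSequence([master_seed, crc32(gene_id)])`, so results are
  independent of gene iteration order and byte-identical across runs;
  the pipeline fans a single seed out to stages the same way.

## The synthetic-data generator

The generator emulates the statistical structure the caller assumes,
with full ground truth; it does not model sequencing error, quality
scores, duplicate reads, mappability or overdispersed counts.

- Genes: `n_genes` non-overlapping spans on one chromosome, lengths
  uniform in `gene_length_range` (default 2–10 kb), strands random,
  separated by 0.5–3 kb intergenic gaps. Each gene gets 1–5 exons by a
  Dirichlet split (50 bp minimum segment). Biotype is lncRNA with
  probability `lncRNA_fraction` (default 0.3), else mRNA; mRNAs carry
  a CDS spanning the middle 70% of exonic bases with 15% UTR flanks,
  oriented by strand.
- Reads: per gene and sample, a Poisson count around
  `background_reads_per_gene` (default 100) of fixed-length reads
  (default 150 bp, truncated at gene ends). Input starts are uniform
  over valid positions. IP starts are drawn from a piecewise-constant
  density with weight `ip_enrichment` (default 8) on the window of
  starts whose read would overlap a planted site and weight 1
  elsewhere — so `ip_enrichment=1` *is* the caller's null, exactly,
  which makes the type-I-error and exchangeability checks sharp by
  construction. An intergenic pool sized to `intergenic_read_fraction`
  of the sample is placed uniformly in the gaps.
- Sites: one `site_width` (default 200 bp) interval per gene, uniform
  within the span.
- Sequences: site sequences are uniform RNA (`ACGU`) with the motif
  (default `GGGAU`) overwritten at a random offset in
  `motif_plant_fraction` of them (positions recorded as ground truth);
  the background is an equal number of independent random sequences.
  A synthetic genome can also be emitted with the motif written in
  plus-strand DNA orientation at site centres so unstranded peak
  extraction recovers it.
- Ct tables: reference-gene Ct constant plus Gaussian noise
  (default sd 0.15 cycles); target Ct sits `control_delta_ct` cycles
  above it in controls and is shifted by `−log2(true_fold_change)` in
  the second group, so 2^-ΔΔCt recovers the planted fold exactly at
  zero noise.

These defaults are the study conditions for all validation: passing
tests demonstrate correctness of the computation and calibration under
uniform background placement, not robustness to the biases of real
libraries (non-uniform coverage, positional effects, duplicates).

## Downstream statistics

- **Region assignment** labels an interval by the base-majority
  category of the gene bases it overlaps, with precedence
  CDS > 3'UTR > 5'UTR > exon > intron on exact ties (the precedence is
  a documented convention, configurable). Distribution tables can be
  computed over reads (default) or peaks.
- **Peak overlap** between two samples is reported from both sides
  (`a_with_overlap`, `b_with_overlap`, pair count), because interval
  overlap is not one-to-one and a single Venn-style intersection
  number depends on the side it is counted from.
- **RPKM** uses the gene span length by default (exon-union length as
  an option) and the sample's total read count as library size unless
  an explicit size is given. Sample correlation is Pearson on
  `log2(RPKM+1)` over the outer-joined gene universe (missing → 0),
  clustered with average linkage on `1 − r`; a zero-variance sample is
  an error naming the sample.
- **K-mer enrichment** counts presence/absence per sequence (an
  occurrences mode exists as a flag), tests each observed k-mer with
  the hypergeometric upper tail of its 2×2 occurrence table, and ranks
  by p, then fold (with a 0.5-count continuity correction when the
  background count is zero), then lexicographically. Default k = 5.
  When no background is supplied, a seeded per-sequence dinucleotide
  shuffle (random Eulerian walk preserving exact dinucleotide counts)
  is used. No PWM refinement is attempted. Note that the *minimum*
  p-value across all 4^k k-mers is expected to be near 1/4^k under the
  null — small smallest-p values in a full table are an order
  statistic, not evidence of a motif; judge candidates by rank
  stability and fold.
- **Gene-set enrichment** computes the hypergeometric upper tail
  (`scipy.stats.hypergeom.sf`, log-space stable) per term and BH FDR
  within each term category (global FDR as a flag), with the universe
  defaulting to all genes in the term map; zero-overlap terms are
  excluded from testing by default (this affects the BH denominator,
  and is logged). Target genes outside the universe are dropped with a
  warning.
- **ΔΔCt** centres per-sample ΔCt on the arithmetic control-group mean
  (Livak formulation: control geometric-mean fold = 1) and reports
  Welch's t on ΔCt for group comparison — a documented choice of test,
  with no amplification-efficiency correction.

## Numerical and scale choices

Null simulation is vectorised: all placements of a gene are drawn as
one integer matrix and swept with a sort-based coverage scan (ends
sort before coincident starts, preserving half-open semantics), so a
200-gene, 500-round run completes in seconds. Validation problem
sizes — 100–500 genes, ~100 reads per gene, 500 placements, 500 site
sequences — were chosen as desk-scale conditions with adequate power
(an 8-fold site at these depths yields heights far above every null
maximum, so planted-site p-values are exactly 0).

## Known limitations

- Empirical p-values are bounded below by 1/n_simulations; genes with
  extreme signal all tie at p = 0, so peak ranking within a gene
  should use height, not p.
- No multiple-testing correction is applied across peaks or genes in
  the caller itself (the upstream procedure defines none); the
  per-gene selection rate, not the family-wise error, is controlled.
- Paired-end mates are treated as independent intervals; fragment
  merging is out of scope.
- The generator's uniform background is the caller's own null; real
  libraries violate it, so real-data peak lists should be interpreted
  with the input-subtraction step doing the heavy lifting.
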