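"""End-to-end orchestration of the analysis stages.

`run_pipeline` strings the stages together the way the underlying
experiment is analysed: peak calling with input subtraction per
condition, cross-condition peak overlap, region/biotype annotation,
RPKM + sample correlation, k-mer motif enrichment on final peak
sequences, gene-set enrichment of peak-associated genes, and ddCt
quantification.  Every output is written under one directory and
listed, with a SHA-256 checksum, in ``manifest.json``; runs with the
same inputs and seed produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import annotation, enrichment, io_formats, motif, peak_calling, quant
from .intervals import Peak
from .peak_calling import PeakCallingConfig

logger = logging.getLogger(__name__)

ALL_STAGES = ("callpeaks", "overlap", "annotate", "expr", "motif",
              "enrich", "ddct")


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run.

    ``ip_beds`` holds one BED per condition (e.g. IP1 = normal,
    IP2 = remodeling); ``input_beds`` holds the matched input(s) — a
    single input is reused for every condition.  Optional inputs gate
    their stages: no genome FASTA -> no motif stage, no term map -> no
    enrichment, no Ct table -> no ddct.
    """

    gtf: Path
    ip_beds: Sequence[Path]
    input_beds: Sequence[Path]
    outdir: Path
    genome_fasta: Optional[Path] = None
    term_map: Optional[Path] = None
    ct_table: Optional[Path] = None
    control_label: str = "control"
    peaks: PeakCallingConfig = field(default_factory=PeakCallingConfig)
    stranded: bool = False
    motif_k: int = 5
    stages: Sequence[str] = ALL_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not self.ip_beds:
            raise ValueError("need at least one IP BED")
        if not self.input_beds:
            raise ValueError("need at least one input BED")


def _stage_seed(master: int, stage: str) -> int:
    # stable per-stage fan-out so stage order does not shift randomness
    return (master * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages; returns the result bundle.

    The bundle maps stage names to their in-memory results and lists
    every file written; ``manifest.json`` in the output directory
    records files, checksums and parameters.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    genes = io_formats.read_gtf(config.gtf)
    written: list[Path] = []
    bundle: dict = {"conditions": [], "files": written}

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    final_peaks: dict[str, list[Peak]] = {}
    reads_by_sample: dict[str, list] = {}

    if "callpeaks" in stages:
        for i, ip_bed in enumerate(config.ip_beds):
            cond = f"IP{i + 1}"
            input_bed = config.input_beds[min(i, len(config.input_beds) - 1)]
            ip_reads = io_formats.read_bed(ip_bed, sample=cond)
            input_reads = io_formats.read_bed(input_bed, sample=f"Input{i + 1}")
            reads_by_sample[cond] = ip_reads
            reads_by_sample[f"Input{i + 1}"] = input_reads

            pk_cfg = replace(config.peaks,
                             seed=_stage_seed(config.seed, f"callpeaks:{cond}"),
                             stranded=config.stranded)
            in_cfg = replace(pk_cfg,
                             seed=_stage_seed(config.seed, f"callpeaks:Input{i + 1}"))
            ip_peaks = peak_calling.call_peaks(ip_reads, genes, pk_cfg)
            input_peaks = peak_calling.call_peaks(input_reads, genes, in_cfg)
            ip_sel = [p for p in ip_peaks if p.selected]
            in_sel = [p for p in input_peaks if p.selected]
            final = peak_calling.subtract_input(ip_sel, in_sel,
                                                stranded=config.stranded)
            final_peaks[cond] = final
            for name, pk in ((f"{cond}_candidates.bed", ip_peaks),
                             (f"{cond}_selected.bed", ip_sel),
                             (f"Input{i + 1}_selected.bed", in_sel),
                             (f"{cond}_final.bed", final)):
                path = outdir / name
                io_formats.write_peaks(pk, path)
                written.append(path)
            logger.info("%s: %d candidate, %d selected, %d after input "
                        "subtraction", cond, len(ip_peaks), len(ip_sel),
                        len(final))
            bundle["conditions"].append(cond)
        bundle["final_peaks"] = final_peaks

    if "overlap" in stages and len(final_peaks) >= 2:
        conds = sorted(final_peaks)
        summary = annotation.peak_overlap(final_peaks[conds[0]],
                                          final_peaks[conds[1]])
        df = pd.DataFrame([{"a": conds[0], "b": conds[1],
                            **summary.__dict__}])
        save_tsv(df, "peak_overlap.tsv")
        bundle["overlap"] = summary
        # per-condition lncRNA peak tables (condition comparison report)
        lnc_genes = {g.gene_id for g in genes if g.biotype == "lncRNA"}
        for cond in conds:
            lnc = [p for p in final_peaks[cond] if p.gene_id in lnc_genes]
            path = outdir / f"{cond}_lncRNA_peaks.bed"
            io_formats.write_peaks(lnc, path)
            written.append(path)

    if "annotate" in stages and reads_by_sample:
        frames = []
        for sample, reads in sorted(reads_by_sample.items()):
            df = annotation.region_distribution(reads, genes)
            df.insert(0, "sample", sample)
            frames.append(df)
        save_tsv(pd.concat(frames, ignore_index=True),
                 "region_distribution.tsv")
        for cond, peaks in sorted(final_peaks.items()):
            save_tsv(annotation.biotype_peak_counts(peaks, genes),
                     f"{cond}_biotype_counts.tsv")

    if "expr" in stages and reads_by_sample:
        expr = {s: annotation.compute_rpkm(r, genes)
                for s, r in sorted(reads_by_sample.items()) if r}
        for s, df in expr.items():
            save_tsv(df, f"{s}_rpkm.tsv")
        if len(expr) >= 2:
            corr, order = annotation.sample_correlation(expr)
            corr.to_csv(outdir / "sample_correlation.tsv", sep="\t")
            written.append(outdir / "sample_correlation.tsv")
            bundle["correlation_order"] = order
        bundle["expr"] = expr

    if "motif" in stages and config.genome_fasta and final_peaks:
        genome = io_formats.read_fasta(config.genome_fasta)
        for cond, peaks in sorted(final_peaks.items()):
            if not peaks:
                continue
            seqs = motif.extract_peak_sequences(
                peaks, genome, stranded=config.stranded
            )
            usable = {k: v for k, v in seqs.items()
                      if len(v) >= config.motif_k}
            if not usable:
                continue
            results = motif.kmer_enrichment(
                usable, None, config.motif_k,
                seed=_stage_seed(config.seed, f"motif:{cond}"),
            )
            save_tsv(pd.DataFrame([r.__dict__ for r in results]),
                     f"{cond}_kmer_enrichment.tsv")
            bundle.setdefault("motif", {})[cond] = results

    if "enrich" in stages and config.term_map and final_peaks:
        term_map = io_formats.read_term_map(config.term_map)
        targets = sorted({p.gene_id for peaks in final_peaks.values()
                          for p in peaks if p.gene_id != "intergenic"})
        df = enrichment.enrich(targets, term_map)
        save_tsv(df, "enrichment.tsv")
        bundle["enrichment"] = df

    if "ddct" in stages and config.ct_table:
        ct = io_formats.read_ct_table(config.ct_table)
        per_sample, summary = quant.delta_delta_ct(ct, config.control_label)
        save_tsv(per_sample, "ddct_per_sample.tsv")
        save_tsv(summary, "ddct_summary.tsv")
        bundle["ddct"] = (per_sample, summary)

    manifest = {
        "seed": config.seed,
        "stages": sorted(stages),
        "parameters": {
            "n_simulations": config.peaks.n_simulations,
            "alpha": config.peaks.alpha,
            "stranded": config.stranded,
            "motif_k": config.motif_k,
        },
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
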