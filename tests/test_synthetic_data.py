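"""The generator: determinism, ground-truth containment, planted signal."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

from ripcall.intervals import GeneModel, GenomicInterval
from ripcall.synthetic_data import (GroundTruth, SimulationConfig,
                                    emit_genome, emit_site_sequences,
                                    make_annotation, make_ct_table,
                                    plant_sites, simulate_reads)


class TestMakeAnnotation:
    def test_zero_genes(self):
        genes, sizes = make_annotation(SimulationConfig(n_genes=0))
        assert genes == [] and sizes["chr1"] > 0

    def test_gene_count_biotypes_and_reproducibility(self):
        cfg = SimulationConfig(n_genes=100, lncRNA_fraction=0.3, seed=5)
        genes, _ = make_annotation(cfg)
        genes2, _ = make_annotation(cfg)
        assert len(genes) == 100
        assert [(g.gene_id, g.interval, g.biotype, g.exons) for g in genes] \
            == [(g.gene_id, g.interval, g.biotype, g.exons) for g in genes2]
        n_lnc = sum(g.biotype == "lncRNA" for g in genes)
        lo, hi = binom.ppf([0.0005, 0.9995], 100, 0.3)
        assert lo <= n_lnc <= hi

    def test_degenerate_length_range(self):
        cfg = SimulationConfig(n_genes=20, gene_length_range=(1000, 1000),
                               site_width=100)
        genes, _ = make_annotation(cfg)
        assert all(g.span_length == 1000 for g in genes)

    def test_genes_non_overlapping_with_gaps(self):
        genes, sizes = make_annotation(SimulationConfig(n_genes=50, seed=2))
        spans = sorted((g.interval.start, g.interval.end) for g in genes)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
        assert spans[-1][1] < sizes["chr1"]

    def test_mrna_has_cds_lncrna_does_not(self):
        genes, _ = make_annotation(SimulationConfig(n_genes=60, seed=3))
        for g in genes:
            if g.biotype == "mRNA":
                assert g.cds
            else:
                assert not g.cds


class TestPlantSites:
    def test_every_site_inside_its_gene(self):
        cfg = SimulationConfig(n_genes=50, n_sites_per_gene=2, seed=4)
        genes, _ = make_annotation(cfg)
        by_id = {g.gene_id: g for g in genes}
        for gene_id, iv in plant_sites(genes, cfg):
            g = by_id[gene_id].interval
            assert g.start <= iv.start and iv.end <= g.end
            assert iv.length == cfg.site_width


def _mean_coverage(reads, interval):
    cov = np.zeros(interval.length)
    for r in reads:
        a = max(r.interval.start, interval.start) - interval.start
        b = min(r.interval.end, interval.end) - interval.start
        if b > a:
            cov[a:b] += 1
    return cov.mean()


class TestSimulateReads:
    def test_site_coverage_exceeds_background(self):
        gene = GeneModel("g1", GenomicInterval("chr1", 0, 10_000, "+"))
        site = GenomicInterval("chr1", 4000, 4200, "+")
        cfg = SimulationConfig(n_genes=1, background_reads_per_gene=500,
                               ip_enrichment=10.0,
                               intergenic_read_fraction=0.0, seed=6)
        ip, inp, _ = simulate_reads([gene], [("g1", site)], cfg)
        inside = _mean_coverage(ip, site)
        outside = _mean_coverage(ip, GenomicInterval("chr1", 6000, 10_000))
        assert inside > 2 * outside
        # input stays flat
        assert _mean_coverage(inp, site) == pytest.approx(
            _mean_coverage(inp, GenomicInterval("chr1", 6000, 10_000)),
            rel=0.5)

    def test_no_background_no_intergenic_gives_empty_input(self):
        cfg = SimulationConfig(n_genes=5, background_reads_per_gene=0,
                               intergenic_read_fraction=0.0, seed=1)
        genes, sizes = make_annotation(cfg)
        _, inp, _ = simulate_reads(genes, [], cfg, sizes)
        assert inp == []

    def test_reads_respect_gene_bounds_and_length(self):
        cfg = SimulationConfig(n_genes=20, seed=8,
                               intergenic_read_fraction=0.0)
        genes, sizes = make_annotation(cfg)
        sites = plant_sites(genes, cfg)
        ip, inp, _ = simulate_reads(genes, sites, cfg, sizes)
        spans = [(g.interval.start, g.interval.end) for g in genes]
        for r in ip + inp:
            assert r.interval.length <= cfg.read_length
            assert any(s <= r.interval.start and r.interval.end <= e
                       for s, e in spans)

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        from ripcall import io_formats
        cfg = SimulationConfig(n_genes=10, seed=9)
        out = []
        for tag in ("a", "b"):
            genes, sizes = make_annotation(cfg)
            sites = plant_sites(genes, cfg)
            ip, inp, truth = simulate_reads(genes, sites, cfg, sizes)
            fg, bg = emit_site_sequences(truth, cfg)
            io_formats.write_bed(ip, tmp_path / f"ip_{tag}.bed")
            io_formats.write_bed(inp, tmp_path / f"in_{tag}.bed")
            io_formats.write_gtf(genes, tmp_path / f"genes_{tag}.gtf")
            io_formats.write_fasta(fg, tmp_path / f"fg_{tag}.fa")
            out.append(tag)
        for name in ("ip", "in"):
            assert (tmp_path / f"{name}_a.bed").read_bytes() == \
                (tmp_path / f"{name}_b.bed").read_bytes()
        assert (tmp_path / "genes_a.gtf").read_bytes() == \
            (tmp_path / "genes_b.gtf").read_bytes()
        assert (tmp_path / "fg_a.fa").read_bytes() == \
            (tmp_path / "fg_b.fa").read_bytes()

    def test_site_wider_than_gene_raises(self):
        gene = GeneModel("g1", GenomicInterval("chr1", 100, 400))
        cfg = SimulationConfig(n_genes=1, gene_length_range=(300, 300),
                               site_width=200, seed=0)
        bad_site = GenomicInterval("chr1", 50, 500)
        with pytest.raises(ValueError):
            simulate_reads([gene], [("g1", bad_site)], cfg)


class TestEmitSiteSequences:
    def _truth(self, n, cfg):
        genes, _ = make_annotation(cfg)
        return GroundTruth(sites=plant_sites(genes, cfg))

    def test_plant_fraction_zero_records_nothing(self):
        cfg = SimulationConfig(n_genes=20, motif_plant_fraction=0.0, seed=1)
        truth = self._truth(20, cfg)
        fg, bg = emit_site_sequences(truth, cfg)
        assert truth.motif_positions == []
        assert len(fg) == len(bg) == 20

    def test_plant_fraction_one_plants_everywhere(self):
        cfg = SimulationConfig(n_genes=50, motif_plant_fraction=1.0, seed=2)
        truth = self._truth(50, cfg)
        fg, _ = emit_site_sequences(truth, cfg)
        assert len(truth.motif_positions) == 50
        assert all("GGGAU" in s for s in fg.values())

    def test_recorded_positions_match_fasta_scan(self):
        """Oracle: scan the emitted sequences for the motif."""
        cfg = SimulationConfig(n_genes=200, motif_plant_fraction=0.4, seed=3)
        truth = self._truth(200, cfg)
        fg, _ = emit_site_sequences(truth, cfg)
        for name, off in truth.motif_positions:
            assert fg[name][off:off + 5] == "GGGAU"
        # reproducible planted count
        truth2 = self._truth(200, cfg)
        emit_site_sequences(truth2, cfg)
        assert len(truth2.motif_positions) == len(truth.motif_positions)

    def test_sequences_use_rna_alphabet(self):
        cfg = SimulationConfig(n_genes=10, seed=4)
        truth = self._truth(10, cfg)
        fg, bg = emit_site_sequences(truth, cfg)
        assert set("".join(fg.values()) + "".join(bg.values())) <= set("ACGU")


class TestEmitGenome:
    def test_motif_planted_at_site_centres(self):
        cfg = SimulationConfig(n_genes=30, motif_plant_fraction=1.0, seed=5)
        genes, sizes = make_annotation(cfg)
        truth = GroundTruth(sites=plant_sites(genes, cfg))
        genome = emit_genome(genes, sizes, truth, cfg)
        assert len(genome["chr1"]) == sizes["chr1"]
        for _, iv in truth.sites:
            mid = (iv.start + iv.end - 5) // 2
            assert genome["chr1"][mid:mid + 5] == "GGGAT"


class TestMakeCtTable:
    def test_fold_one_no_noise_identical_groups(self):
        t = make_ct_table(3, 1.0, noise_sd=0.0)
        means = t.groupby("group")["target_ct"].mean()
        assert means.nunique() == 1

    def test_quarter_fold_no_noise_is_two_cycles_up(self):
        t = make_ct_table(3, 0.25, noise_sd=0.0)
        means = t.groupby("group")["target_ct"].mean()
        assert means["remodeling"] - means["control"] == pytest.approx(2.0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            make_ct_table(0, 1.0)
        with pytest.raises(ValueError):
            make_ct_table(3, -1.0)
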