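"""Shared fixtures: small gene models and synthetic datasets."""

from __future__ import annotations

import pytest

from ripcall.intervals import GeneModel, GenomicInterval
from ripcall.peak_calling import PeakCallingConfig
from ripcall.synthetic_data import (SimulationConfig, make_annotation,
                                    plant_sites, simulate_reads)


@pytest.fixture
def coding_gene() -> GeneModel:
    """A two-exon plus-strand mRNA with UTRs flanking the CDS.

    Layout on chr1: exon1 [1000,1400) (5'UTR [1000,1200) + CDS
    [1200,1400)), intron [1400,1600), exon2 [1600,2000) (CDS
    [1600,1800) + 3'UTR [1800,2000)).
    """
    return GeneModel(
        "geneA",
        GenomicInterval("chr1", 1000, 2000, "+"),
        "mRNA",
        exons=(GenomicInterval("chr1", 1000, 1400, "+"),
               GenomicInterval("chr1", 1600, 2000, "+")),
        cds=(GenomicInterval("chr1", 1200, 1400, "+"),
             GenomicInterval("chr1", 1600, 1800, "+")),
    )


@pytest.fixture
def lnc_gene() -> GeneModel:
    return GeneModel(
        "geneB",
        GenomicInterval("chr1", 5000, 8000, "-"),
        "lncRNA",
        exons=(GenomicInterval("chr1", 5000, 6000, "-"),
               GenomicInterval("chr1", 7000, 8000, "-")),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by read-level tests."""
    cfg = SimulationConfig(n_genes=30, background_reads_per_gene=60,
                           seed=0)
    genes, chrom_sizes = make_annotation(cfg)
    sites = plant_sites(genes, cfg)
    ip, inp, truth = simulate_reads(genes, sites, cfg, chrom_sizes)
    return cfg, genes, chrom_sizes, sites, ip, inp, truth


@pytest.fixture(scope="session")
def fast_peak_config() -> PeakCallingConfig:
    return PeakCallingConfig(n_simulations=200, seed=0)
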