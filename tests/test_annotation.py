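"""Region assignment, biotype counts, overlap summaries, RPKM, correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ripcall.annotation import (OverlapSummary, assign_region,
                                biotype_peak_counts, compute_rpkm,
                                peak_overlap, region_distribution,
                                sample_correlation)
from ripcall.intervals import AlignedRead, GeneModel, GenomicInterval, Peak


def _iv(s, e, chrom="chr1", strand="."):
    return GenomicInterval(chrom, s, e, strand)


class TestAssignRegion:
    def test_between_genes_is_intergenic(self, coding_gene):
        assert assign_region(_iv(100, 200), [coding_gene]) == "intergenic"

    def test_fully_inside_intron(self, coding_gene):
        assert assign_region(_iv(1450, 1550), [coding_gene]) == "intron"

    def test_base_majority_wins(self, coding_gene):
        # [1340, 1440): 60 bp CDS + 40 bp intron -> CDS
        assert assign_region(_iv(1340, 1440), [coding_gene]) == "CDS"
        # [1360, 1460): 40 bp CDS + 60 bp intron -> intron
        assert assign_region(_iv(1360, 1460), [coding_gene]) == "intron"

    def test_utr_orientation_follows_strand(self, coding_gene):
        assert assign_region(_iv(1000, 1100), [coding_gene]) == "5'UTR"
        assert assign_region(_iv(1850, 1950), [coding_gene]) == "3'UTR"

    def test_noncoding_exon_label(self, lnc_gene):
        assert assign_region(_iv(5100, 5200), [lnc_gene]) == "exon"

    def test_tie_breaks_by_precedence(self, coding_gene):
        # [1350, 1450): exactly 50 bp CDS and 50 bp intron -> CDS wins
        assert assign_region(_iv(1350, 1450), [coding_gene]) == "CDS"

    def test_majority_oracle_on_random_intervals(self, coding_gene, lnc_gene):
        """Per-base counting oracle over random query intervals."""
        genes = [coding_gene, lnc_gene]
        base_label = {}
        for g in genes:
            for cat, ivs in (("exon_or_utr", g.exons),):
                pass
        # oracle: label every base explicitly
        def oracle(iv):
            from ripcall.annotation import _gene_category_intervals, REGION_LABELS
            counts = {}
            for g in genes:
                for cat, sub in _gene_category_intervals(g):
                    for b in range(max(iv.start, sub.start),
                                   min(iv.end, sub.end)):
                        counts[cat] = counts.get(cat, 0) + 1
            if not counts:
                return "intergenic"
            rank = {l: i for i, l in enumerate(REGION_LABELS)}
            return max(counts, key=lambda c: (counts[c], -rank[c]))

        rng = np.random.default_rng(0)
        for _ in range(200):
            s = int(rng.integers(0, 8100))
            iv = _iv(s, s + int(rng.integers(1, 400)))
            assert assign_region(iv, genes) == oracle(iv)


class TestRegionDistribution:
    def test_all_intergenic_single_row(self, coding_gene):
        df = region_distribution([_iv(0, 10), _iv(20, 30)], [coding_gene])
        assert list(df["region"]) == ["intergenic"]
        assert df["fraction"].iloc[0] == 1.0

    def test_fractions_sum_to_one_and_counts_conserved(self, small_dataset):
        _, genes, _, _, ip, _, _ = small_dataset
        df = region_distribution(ip, genes)
        assert df["count"].sum() == len(ip)
        assert abs(df["fraction"].sum() - 1.0) < 1e-12

    def test_empty_input_empty_table(self, coding_gene):
        assert region_distribution([], [coding_gene]).empty


class TestBiotypeCounts:
    def test_counts_match_ground_truth_annotation(self, small_dataset):
        _, genes, _, _, _, _, _ = small_dataset
        biotype_of = {g.gene_id: g.biotype for g in genes}
        rng = np.random.default_rng(1)
        peaks = []
        for i, g in enumerate(rng.choice(genes, size=40)):
            s = g.interval.start
            peaks.append(Peak(_iv(s, s + 10, strand=g.interval.strand),
                              f"p{i}", 1, 1, g.gene_id))
        peaks.append(Peak(_iv(0, 10), "pX", 1, 1, "intergenic"))
        df = biotype_peak_counts(peaks, genes).set_index("biotype")
        expected = pd.Series([biotype_of[p.gene_id]
                              for p in peaks[:-1]]).value_counts()
        for bt in ("mRNA", "lncRNA"):
            assert df.loc[bt, "peak_count"] == int(expected.get(bt, 0))
        assert df.loc["intergenic", "peak_count"] == 1
        assert df["peak_count"].sum() == len(peaks)

    def test_empty_peaks_all_zero(self, small_dataset):
        _, genes, _, _, _, _, _ = small_dataset
        df = biotype_peak_counts([], genes)
        assert (df["peak_count"] == 0).all()


def _peaks(spans, prefix="p"):
    return [Peak(_iv(s, e), f"{prefix}{i}", 1, 1)
            for i, (s, e) in enumerate(spans)]


class TestPeakOverlap:
    def test_identical_sets(self):
        a = _peaks([(0, 10), (20, 30)])
        s = peak_overlap(a, a)
        assert s.a_with_overlap == s.b_with_overlap == 2
        assert s.n_a_only == s.n_b_only == 0

    def test_disjoint_sets(self):
        s = peak_overlap(_peaks([(0, 10)]), _peaks([(50, 60), (70, 80)]))
        assert s == OverlapSummary(1, 2, 0, 0, 0)

    def test_one_to_many_counted_from_both_sides(self):
        s = peak_overlap(_peaks([(100, 200)]),
                         _peaks([(150, 160), (180, 300)]))
        assert (s.a_with_overlap, s.b_with_overlap, s.n_overlapping_pairs) \
            == (1, 2, 2)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(2)
        a = _peaks([(int(s), int(s) + int(rng.integers(1, 100)))
                    for s in rng.integers(0, 3000, 30)], "a")
        b = _peaks([(int(s), int(s) + int(rng.integers(1, 100)))
                    for s in rng.integers(0, 3000, 30)], "b")
        s1, s2 = peak_overlap(a, b), peak_overlap(b, a)
        assert (s1.a_with_overlap, s1.b_with_overlap, s1.n_a_only,
                s1.n_b_only) == (s2.b_with_overlap, s2.a_with_overlap,
                                 s2.n_b_only, s2.n_a_only)
        assert s1.n_overlapping_pairs == s2.n_overlapping_pairs

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        a = _peaks([(int(s), int(s) + int(rng.integers(1, 200)))
                    for s in rng.integers(0, 5000, 50)], "a")
        b = _peaks([(int(s), int(s) + int(rng.integers(1, 200)))
                    for s in rng.integers(0, 5000, 50)], "b")
        pairs = sum(pa.interval.overlaps(pb.interval)
                    for pa in a for pb in b)
        a_hit = sum(any(pa.interval.overlaps(pb.interval) for pb in b)
                    for pa in a)
        b_hit = sum(any(pb.interval.overlaps(pa.interval) for pa in a)
                    for pb in b)
        s = peak_overlap(a, b)
        assert (s.n_overlapping_pairs, s.a_with_overlap, s.b_with_overlap) \
            == (pairs, a_hit, b_hit)


class TestRpkm:
    def test_hand_arithmetic(self):
        gene = GeneModel("g", _iv(0, 2000))
        reads = [AlignedRead(_iv(10, 100), f"r{i}") for i in range(10)]
        df = compute_rpkm(reads, [gene], library_size=1_000_000)
        assert df.loc[0, "rpkm"] == pytest.approx(5.0)

    def test_zero_reads_on_gene_gives_zero(self):
        genes = [GeneModel("g1", _iv(0, 2000)), GeneModel("g2", _iv(5000, 7000))]
        reads = [AlignedRead(_iv(10, 100), "r0")]
        df = compute_rpkm(reads, genes).set_index("gene_id")
        assert df.loc["g2", "rpkm"] == 0.0

    def test_doubling_library_halves_rpkm(self):
        gene = GeneModel("g", _iv(0, 2000))
        reads = [AlignedRead(_iv(10, 100), f"r{i}") for i in range(10)]
        a = compute_rpkm(reads, [gene], library_size=10_000)
        b = compute_rpkm(reads, [gene], library_size=20_000)
        assert np.allclose(a["rpkm"], 2 * b["rpkm"])

    def test_empty_reads_raise(self):
        with pytest.raises(ValueError):
            compute_rpkm([], [GeneModel("g", _iv(0, 100))])


class TestSampleCorrelation:
    @staticmethod
    def _table(vals):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(vals))],
                             "read_count": 0, "gene_length": 1000,
                             "rpkm": vals})

    def test_identical_samples_have_unit_correlation(self):
        t = self._table([1.0, 5.0, 10.0, 0.0])
        corr, _ = sample_correlation({"a": t, "b": t.copy()})
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.gamma(2, 5, 50), rng.gamma(2, 5, 50)
        corr, _ = sample_correlation({"a": self._table(x),
                                      "b": self._table(y)})
        lx, ly = np.log2(x + 1), np.log2(y + 1)
        expected = (np.mean(lx * ly) - lx.mean() * ly.mean()) / \
            (lx.std() * ly.std())
        assert corr.loc["a", "b"] == pytest.approx(expected)

    def test_matrix_symmetric_unit_diagonal_psd(self):
        rng = np.random.default_rng(6)
        tables = {f"s{i}": self._table(rng.gamma(2, 5, 40))
                  for i in range(4)}
        corr, order = sample_correlation(tables)
        m = corr.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.linalg.eigvalsh(m).min() > -1e-10
        assert sorted(order) == sorted(tables)

    def test_identical_pairs_cluster_together(self):
        rng = np.random.default_rng(7)
        x, y = rng.gamma(2, 5, 40), rng.gamma(2, 5, 40)
        tables = {"a1": self._table(x), "b1": self._table(y),
                  "a2": self._table(x), "b2": self._table(y)}
        _, order = sample_correlation(tables)
        pos = {s: i for i, s in enumerate(order)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_constant_sample_raises_naming_it(self):
        t1 = self._table([1.0, 2.0, 3.0])
        t2 = self._table([4.0, 4.0, 4.0])
        with pytest.raises(ValueError, match="flat"):
            sample_correlation({"ok": t1, "flat": t2})
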