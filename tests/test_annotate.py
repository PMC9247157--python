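"""TSS-relative annotation, random-region null, chi-square and cutpeaks."""

import numpy as np
import pytest

from chirplex.annotate import (PeakAnnotator, RandomizationParams,
                               RegionScheme, benjamini_hochberg, chisq_2x2,
                               classify_overlap, cut_peaks, empirical_pvalue,
                               feature_distribution, fold_enrichment,
                               sample_random_regions, tss_profile)
from chirplex.intervals import GenomicInterval, RegionSet
from chirplex.io import GeneRecord


@pytest.fixture
def genes():
    return [
        GeneRecord("gPlus", "chr1", "+", 10_000, 12_000),
        GeneRecord("gMinus", "chr1", "-", 30_000, 28_000),
        GeneRecord("gFar", "chr2", "+", 50_000, 52_000),
    ]


class TestAssignFeature:
    def test_plus_strand_proximal_window(self, genes):
        ann = PeakAnnotator(genes)
        cat, gene = ann.assign(GenomicInterval("chr1", 9_000, 9_200))
        assert cat == "Proximal Region" and gene.gene_id == "gPlus"
        # window is [8500, 10500)
        assert ann.assign(GenomicInterval("chr1", 8_400, 8_500))[0] != \
            "Proximal Region"
        assert ann.assign(GenomicInterval("chr1", 8_400, 8_501))[0] == \
            "Proximal Region"

    def test_minus_strand_window_is_reflected(self, genes):
        ann = PeakAnnotator(genes)
        # for TSS 30000 on -, proximal is genomic [29500, 31500)
        cat, gene = ann.assign(GenomicInterval("chr1", 31_000, 31_200))
        assert cat == "Proximal Region" and gene.gene_id == "gMinus"

    def test_priority_proximal_over_intron(self, genes):
        # peak overlapping gPlus's proximal window and gMinus's body
        ann = PeakAnnotator(genes + [
            GeneRecord("gHost", "chr1", "+", 5_000, 9_500)])
        cat, gene = ann.assign(GenomicInterval("chr1", 9_000, 9_200))
        assert cat == "Proximal Region"

    def test_downstream_and_intergenic(self, genes):
        ann = PeakAnnotator(genes)
        assert ann.assign(GenomicInterval("chr1", 13_000, 13_100))[0] == \
            "Downstream"
        assert ann.assign(GenomicInterval("chr1", 100_000, 100_500))[0] == \
            "Distal Intergenic"

    def test_utr_exon_priority_with_subannotation(self, genes):
        utr5 = RegionSet("u5", [GenomicInterval("chr1", 10_600, 10_700, "+",
                                                "gPlus")])
        ann = PeakAnnotator(genes, utr5=utr5)
        assert ann.assign(GenomicInterval("chr1", 10_600, 10_650))[0] == "5'UTR"


class TestFeatureDistribution:
    def test_all_intergenic(self, genes):
        peaks = [GenomicInterval("chr3", 1_000 + i * 10_000, 1_500 + i * 10_000)
                 for i in range(10)]
        df = feature_distribution(peaks, genes)
        assert df.loc[df.category == "Distal Intergenic", "percent"].item() == 100.0

    def test_empty_peaks_no_division_error(self, genes):
        df = feature_distribution([], genes)
        assert df["count"].sum() == 0 and df["percent"].sum() == 0.0

    def test_percentages_sum_to_100(self, small_bundle):
        from chirplex.consensus import find_consensus_peaks
        peaks = [p.interval for p in
                 find_consensus_peaks(small_bundle.replicate_peaks)]
        df = feature_distribution(peaks, small_bundle.genes)
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_realized_proximal_matches_generator_target(self, default_bundle):
        peaks = default_bundle.true_peak_regions()
        df = feature_distribution(peaks.intervals, default_bundle.genes)
        got = df.loc[df.category == "Proximal Region", "percent"].item()
        assert abs(got / 100 - default_bundle.config.proximal_fraction) < 0.01


class TestRandomRegions:
    def test_lengths_and_determinism(self, small_bundle):
        sizes = small_bundle.chrom_sizes
        params = RandomizationParams(1, 10, 775, seed=4)
        lists = sample_random_regions(params, sizes)
        assert len(lists) == 1 and len(lists[0]) == 10
        assert all(len(iv) == 775 for iv in lists[0])
        again = sample_random_regions(params, sizes)
        assert [(i.chrom, i.start) for i in lists[0]] == \
            [(i.chrom, i.start) for i in again[0]]

    def test_proximal_only_all_annotate_proximal(self, small_bundle):
        params = RandomizationParams(1, 100, 775, seed=1, proximal_only=True)
        lists = sample_random_regions(params, small_bundle.chrom_sizes,
                                      small_bundle.genes)
        df = feature_distribution(lists[0].intervals, small_bundle.genes)
        assert df.loc[df.category == "Proximal Region", "percent"].item() == 100.0

    def test_proximal_only_without_genes_is_error(self):
        with pytest.raises(ValueError, match="genes"):
            sample_random_regions(
                RandomizationParams(1, 5, 100, proximal_only=True),
                {"chr1": 10_000})


class TestChiSquare:
    def test_identical_rows(self):
        stat, p = chisq_2x2(10, 90, 10, 90)
        assert stat == 0 and p == 1

    def test_closed_form_value(self):
        stat, _ = chisq_2x2(30, 70, 10, 90)
        assert stat == pytest.approx(12.5)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, 4))
            stat, _ = chisq_2x2(a, b, c, d)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(expected, abs=1e-10)

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2(0, 0, 5, 5)

    def test_printed_proximal_table(self):
        """10.23% of 5,064 peaks vs 8.02% of 5,000 averaged random regions."""
        a = round(0.1023 * 5064)
        c = round(0.0802 * 5000)
        _, p = chisq_2x2(a, 5064 - a, c, 5000 - c)
        assert p == pytest.approx(1.23e-4, rel=0.05)
        assert fold_enrichment(10.23, 8.02) == pytest.approx(1.3, abs=0.05)


class TestEmpiricalP:
    def test_observed_above_all_lists(self):
        fr = np.linspace(0.01, 0.09, 1000)
        assert empirical_pvalue(0.10, fr) == pytest.approx(1 / 1001)

    def test_observed_at_median(self):
        fr = np.linspace(0.0, 0.2, 999)
        p = empirical_pvalue(0.1, fr)
        assert abs(p - 0.5) < 0.01

    def test_depletion_alternative(self):
        fr = np.linspace(0.05, 0.09, 100)
        assert empirical_pvalue(0.01, fr, alternative="less") == \
            pytest.approx(1 / 101)

    def test_paper_variant_all_lists_significant(self):
        # observed 30% vs 1000 lists at ~8%: every per-list chi-square is
        # significant after BH, so p = 1/1000
        fr = np.full(1000, 0.08)
        p = empirical_pvalue(0.30, fr, "paper", n_observed=5000,
                             list_size=5000)
        assert p == pytest.approx(0.001)

    def test_paper_variant_no_significant_lists(self):
        fr = np.full(100, 0.1)
        assert empirical_pvalue(0.1, fr, "paper", n_observed=5000,
                                list_size=5000) == 1.0

    def test_null_calibration_of_standard_variant(self):
        """Rejection rate at 0.05 stays inside the 99% binomial CI when the
        observed list is exchangeable with the random lists."""
        rng = np.random.default_rng(17)
        n_sim, rejections = 200, 0
        for _ in range(n_sim):
            fracs = rng.binomial(2000, 0.08, size=100) / 2000
            obs = rng.binomial(2000, 0.08) / 2000
            if empirical_pvalue(obs, fracs) <= 0.05:
                rejections += 1
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < ci + 0.02  # + tie slack

    def test_bh_monotone(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.5, 0.04])
        assert (np.diff(adj[np.argsort([0.01, 0.02, 0.5, 0.04])]) >= 0).all()
        assert (adj <= 1).all()


class TestTssProfileAndCutpeaks:
    def test_peak_centered_on_tss(self):
        genes = [GeneRecord("g", "chr1", "+", 10_000, 12_000)]
        peaks = [GenomicInterval("chr1", 9_950, 10_050)]
        prof = tss_profile(peaks, genes, window=1000, binsize=100)
        assert prof.loc[-100] == 1 and prof.loc[0] == 1
        assert prof.sum() == 2

    def test_empty_profile(self):
        genes = [GeneRecord("g", "chr1", "+", 10_000, 12_000)]
        prof = tss_profile([], genes, window=1000, binsize=100)
        assert prof.sum() == 0

    def test_binsize_must_divide(self):
        with pytest.raises(ValueError):
            tss_profile([], [GeneRecord("g", "chr1", "+", 1, 2)],
                        window=1000, binsize=300)

    def test_region1_planted_peaks_give_upstream_mass(self, default_bundle):
        """Triplex peaks are planted in region 1; their profile mass upstream
        of -500 dominates the region-2 window."""
        genes = default_bundle.genes
        tri = {p["name"] for p in default_bundle.manifest["true_peaks"]
               if p["is_triplex"]}
        peaks = [iv for iv in default_bundle.true_peak_regions()
                 if iv.name in tri]
        prof = tss_profile(peaks, genes, window=1500, binsize=100)
        up = prof.loc[-1500:-600].sum()
        down = prof.loc[0:1400].sum()
        assert up > 3 * max(down, 1)

    def test_cutpeak_boundary_split(self):
        gene = GeneRecord("g", "chr1", "+", 10_000, 12_000)
        peak = GenomicInterval("chr1", 9_300, 9_700, name="p")
        cp1 = cut_peaks([(peak, gene)], "region1")
        cp2 = cut_peaks([(peak, gene)], "region2")
        assert (cp1[0].interval.start, cp1[0].interval.end) == (9_300, 9_500)
        assert (cp2[0].interval.start, cp2[0].interval.end) == (9_500, 9_700)

    def test_cutpeak_empty_intersection_dropped(self):
        gene = GeneRecord("g", "chr1", "+", 10_000, 12_000)
        peak = GenomicInterval("chr1", 8_700, 9_300, name="p")
        assert cut_peaks([(peak, gene)], "region1")
        assert cut_peaks([(peak, gene)], "region2") == []

    def test_cutpeaks_partition_proximal_intersection(self):
        """region1 + region2 cutpeaks cover peak ∩ proximal window exactly,
        with no double-covered base."""
        rng = np.random.default_rng(6)
        gene_p = GeneRecord("gp", "chr1", "+", 50_000, 52_000)
        gene_m = GeneRecord("gm", "chr1", "-", 90_000, 88_000)
        scheme = RegionScheme()
        for gene in (gene_p, gene_m):
            lo, hi = scheme.proximal_window(gene)
            for _ in range(50):
                s = int(rng.integers(lo - 1_000, hi + 1_000))
                e = s + int(rng.integers(50, 1_500))
                peak = GenomicInterval("chr1", s, e, name="p")
                pieces = (cut_peaks([(peak, gene)], "region1")
                          + cut_peaks([(peak, gene)], "region2"))
                covered = sorted(
                    p for c in pieces
                    for p in range(c.interval.start, c.interval.end))
                expected = sorted(range(max(s, lo), min(e, hi)))
                assert covered == expected  # exact cover, no duplicates


class TestClassifyOverlap:
    gene = GeneRecord("g", "chr1", "+", 10_000, 12_000)

    def _one(self, start, end):
        df = classify_overlap([(GenomicInterval("chr1", start, end), self.gene)])
        return df.loc[df["count"] > 0, "class"].item()

    def test_include_feature(self):
        assert self._one(9_200, 10_600) == "includeFeature"

    def test_overlap_start(self):
        assert self._one(9_200, 9_900) == "overlapStart"

    def test_inside(self):
        assert self._one(9_600, 10_400) == "inside"

    def test_overlap_end(self):
        assert self._one(10_200, 10_700) == "overlapEnd"

    def test_region1_only_is_the_remainder(self):
        df = classify_overlap(
            [(GenomicInterval("chr1", 8_700, 9_300), self.gene),
             (GenomicInterval("chr1", 9_200, 10_600), self.gene)])
        assert df.loc[df["class"] == "region1Only", "count"].item() == 1
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_minus_strand_orientation(self):
        gene = GeneRecord("g", "chr1", "-", 10_000, 8_000)
        # genomic [10200, 10800) is upstream (region 1 side) for a minus gene
        df = classify_overlap([(GenomicInterval("chr1", 9_300, 10_800), gene)])
        assert df.loc[df["count"] > 0, "class"].item() == "includeFeature"
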