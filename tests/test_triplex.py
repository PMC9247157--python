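"""Triplex search: motif tables, masking, TTS/hit oracles, DBDs, tests."""

import numpy as np
import pytest

from chirplex.intervals import GenomicInterval, RegionSet
from chirplex.io import SequenceRecord
from chirplex.synth import SyntheticConfig, generate_bundle
from chirplex.triplex import (TriplexParams, find_triplex_hits, find_tts,
                              mask_rna, merge_dbds, promoter_test, region_test,
                              revcomp, score_window)

from _oracles import oracle_hits, oracle_tts
from conftest import small_config


def _region(dna, name="r1", chrom="c"):
    return RegionSet("rs", [GenomicInterval(chrom, 0, len(dna), name=name)])


def _hitset(hits):
    return {(h.rna_start - 1, h.rna_end, h.dna.start, h.dna.end,
             h.dna.strand, h.mismatches): h.motif for h in hits}


NO_G = TriplexParams(min_guanine_rate=0.0)


class TestMaskRna:
    def test_bases_below_threshold_masked(self):
        assert mask_rna(SequenceRecord("r", "ACG", "RNA"),
                        [0.05, 0.50, 0.95], 0.10) == "NCG"

    def test_zero_threshold_vacuous(self):
        assert mask_rna("ACGU", [0.0, 0.0, 1.0, 0.5], 0.0) == "ACGU"

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            mask_rna("ACGU", [0.5, 0.5])


class TestScoreWindow:
    def test_pyrimidine_perfect(self):
        assert score_window("UUUUU", "AAAAA", "pyrimidine_parallel") == 0
        assert score_window("UCUCU", "AGAGA", "pyrimidine_parallel") == 0

    def test_purine_motif_has_no_GA_triplet(self):
        assert score_window("GGGGG", "AAAAA", "purine_antiparallel") == 5
        assert score_window("GGGGG", "GGGGG", "purine_antiparallel") == 0

    def test_antiparallel_reads_rna_reversed(self):
        # RNA 3'->5' against purine strand: only the reversed read matches
        assert score_window("AAGGG", "GGGAA", "purine_antiparallel") == 0
        assert score_window("AAGGG", "AAGGG", "purine_antiparallel") == 4

    def test_masked_base_always_mismatch(self):
        assert score_window("UNUUU", "AAAAA", "pyrimidine_parallel") == 1

    def test_against_table_lookup_oracle(self):
        table = {
            "pyrimidine_parallel": {("U", "A"), ("C", "G")},
            "purine_antiparallel": {("A", "A"), ("G", "G")},
            "GT_parallel": {("G", "G"), ("U", "A")},
            "GT_antiparallel": {("G", "G"), ("U", "A")},
        }
        rng = np.random.default_rng(9)
        for _ in range(500):
            motif = str(rng.choice(list(table)))
            rna = "".join(rng.choice(list("ACGU"), 30))
            dna = "".join(rng.choice(list("ACGT"), 30))
            r = rna[::-1] if motif.endswith("antiparallel") else rna
            expected = sum((a, b) not in table[motif] for a, b in zip(r, dna))
            assert score_window(rna, dna, motif) == expected


class TestFindTts:
    def test_pure_purine_tract(self):
        out = find_tts("GGGGAGGGGAGGGGG")
        assert [(t.start, t.end, t.purine_strand) for t in out] == [(0, 15, "+")]

    def test_minus_strand_tract(self):
        out = find_tts("CCCCTCCCCTCCCCC")
        assert [(t.start, t.end, t.purine_strand) for t in out] == [(0, 15, "-")]
        assert out[0].purine_seq == revcomp("CCCCTCCCCTCCCCC")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            find_tts("ACGTN" * 4)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(60):
            n = int(rng.integers(50, 200))
            dna = "".join(rng.choice(list("ACGT"),
                                     p=[.3, .2, .3, .2], size=n))
            got = {(t.start, t.end, t.purine_strand) for t in find_tts(dna)}
            assert got == oracle_tts(dna), f"trial {trial}"


class TestFindTriplexHits:
    def test_poly_u_single_hit(self):
        hits = find_triplex_hits("UUUUUUUUUUUUUUU",
                                 _region("AAAAAAAAAAAAAAA"),
                                 {"c": "AAAAAAAAAAAAAAA"}, NO_G)
        assert len(hits) == 1
        h = hits[0]
        assert (h.motif, h.length, h.mismatches, h.dna.strand) == \
            ("pyrimidine_parallel", 15, 0, "+")

    def test_no_candidate_tract_no_hits(self):
        dna = "ACTG" * 10  # no purine tract at 80% purity
        hits = find_triplex_hits("UCUCUCUCUCUCUCUC", _region(dna),
                                 {"c": dna}, NO_G)
        assert hits == []

    def test_short_rna_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            hits = find_triplex_hits("UUUU", _region("A" * 30),
                                     {"c": "A" * 30}, NO_G)
        assert hits == []

    def test_guanine_filter_applies_to_tfo(self):
        dna = "AAAAAAAAAAAAAAA"
        with_g = find_triplex_hits("UUUUUUUUUUUUUUU", _region(dna),
                                   {"c": dna}, TriplexParams())
        assert with_g == []  # poly-U TFO has zero guanine

    def test_missing_chromosome_is_error(self):
        with pytest.raises(KeyError):
            find_triplex_hits("U" * 20, _region("A" * 30), {"other": "A" * 30},
                              NO_G)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        R = int(rng.integers(40, 90))
        D = int(rng.integers(120, 300))
        rna = "".join(rng.choice(list("ACGU"), size=R))
        dna = "".join(rng.choice(list("ACGT"), size=D))
        if trial % 3 == 0:  # plant a matching pair
            L = int(rng.integers(15, 30))
            core = "".join(rng.choice(list("UG"), size=L))
            pr = int(rng.integers(0, R - L + 1))
            pd = int(rng.integers(0, D - L + 1))
            rna = rna[:pr] + core + rna[pr + L:]
            dna = dna[:pd] + core.replace("U", "A") + dna[pd + L:]
        if trial % 5 == 0:  # masked stretch
            rna = rna[:10] + "NNN" + rna[13:]
        params = TriplexParams()
        hits = find_triplex_hits(rna, _region(dna), {"c": dna}, params)
        assert _hitset(hits) == oracle_hits(rna, dna)

    def test_revcomp_invariance(self):
        """Reverse-complementing the region swaps strand labels only."""
        rng = np.random.default_rng(55)
        for _ in range(10):
            rna = "".join(rng.choice(list("ACGU"), size=60))
            core = "".join(rng.choice(list("UG"), size=20))
            rna = rna[:20] + core + rna[40:]
            dna = "".join(rng.choice(list("ACGT"), size=200))
            dna = dna[:90] + core.replace("U", "A") + dna[110:]
            fwd = find_triplex_hits(rna, _region(dna), {"c": dna}, NO_G)
            rc_dna = revcomp(dna)
            rev = find_triplex_hits(rna, _region(rc_dna), {"c": rc_dna}, NO_G)
            D = len(dna)
            flip = {"+": "-", "-": "+"}
            key_f = {(h.rna_start, h.rna_end, h.dna.start, h.dna.end,
                      h.dna.strand, h.mismatches) for h in fwd}
            key_r = {(h.rna_start, h.rna_end, D - h.dna.end, D - h.dna.start,
                      flip[h.dna.strand], h.mismatches) for h in rev}
            assert key_f == key_r

    def test_min_length_monotonicity(self):
        rng = np.random.default_rng(77)
        rna = "".join(rng.choice(list("ACGU"), size=80))
        core = "".join(rng.choice(list("UG"), size=25))
        rna = rna[:30] + core + rna[55:]
        dna = "".join(rng.choice(list("ACGT"), size=300))
        dna = dna[:100] + core.replace("U", "A") + dna[125:]
        h15 = find_triplex_hits(rna, _region(dna), {"c": dna},
                                TriplexParams(min_length=15))
        h20 = find_triplex_hits(rna, _region(dna), {"c": dna},
                                TriplexParams(min_length=20))
        assert len(h20) <= len(h15)
        assert all(h.length >= 20 for h in h20)

    def test_masking_only_removes_coverage(self, small_bundle):
        """Every masked hit lies inside some unmasked hit on the same
        diagonal and strand; masking never creates new triplex pairings."""
        b = small_bundle
        peaks = b.true_peak_regions()
        params = TriplexParams()
        unmasked = find_triplex_hits(b.lncrna.sequence, peaks, b.genome, params)
        masked = find_triplex_hits(mask_rna(b.lncrna, b.profile), peaks,
                                   b.genome, params)
        un = [(h.rna_start, h.rna_end, h.dna, h.dna.strand) for h in unmasked]
        for h in masked:
            contained = any(
                rs <= h.rna_start and h.rna_end <= re
                and d.chrom == h.dna.chrom and d.strand == h.dna.strand
                and d.start <= h.dna.start and h.dna.end <= d.end
                for rs, re, d, _ in un)
            assert contained


class TestMergeDbds:
    def test_overlap_union(self):
        from chirplex.triplex import TriplexHit
        hits = [
            TriplexHit(119, 150, GenomicInterval("c", 0, 31), "GT_parallel",
                       31, 0, "a"),
            TriplexHit(140, 196, GenomicInterval("c", 50, 106), "GT_parallel",
                       56, 0, "b"),
        ]
        dbds = merge_dbds(hits, 10)
        assert [(d.rna_start, d.rna_end) for d in dbds] == [(119, 196)]
        assert dbds[0].n_supporting_regions == 2

    def test_distant_tfos_stay_separate(self):
        from chirplex.triplex import TriplexHit
        hits = [
            TriplexHit(47, 70, GenomicInterval("c", 0, 24), "GT_parallel",
                       24, 0, "a"),
            TriplexHit(119, 196, GenomicInterval("c", 50, 127), "GT_parallel",
                       77, 0, "a"),
        ]
        assert len(merge_dbds(hits, 10)) == 2

    def test_gap_boundary(self):
        from chirplex.triplex import TriplexHit
        mk = lambda s, e: TriplexHit(s, e, GenomicInterval("c", 0, e - s + 1),
                                     "GT_parallel", e - s + 1, 0, "a")
        # gap between [10,20] and [30,40] is 9 < merge_gap 10 -> merged
        assert len(merge_dbds([mk(10, 20), mk(30, 40)], 10)) == 1
        assert len(merge_dbds([mk(10, 20), mk(31, 40)], 10)) == 2


class TestRegionAndPromoterTests:
    def test_no_tfo_rna_gives_p_one(self, small_bundle):
        res = region_test("ACAC" * 30, small_bundle.true_peak_regions(),
                          small_bundle.genome, 19, TriplexParams(), seed=0)
        assert res[0].observed == 0 and res[0].p == 1.0

    def test_planted_targets_hit_p_floor(self, small_bundle):
        b = small_bundle
        tri = {p["name"] for p in b.manifest["true_peaks"] if p["is_triplex"]}
        targets = RegionSet("t", [iv for iv in b.true_peak_regions()
                                  if iv.name in tri])
        rna = mask_rna(b.lncrna, b.profile)
        res = region_test(rna, targets, b.genome, 99, TriplexParams(), seed=1)
        assert res[0].observed == len(targets)
        assert res[0].p == pytest.approx(1 / 100)
        assert res[0].z is None or res[0].z > 3

    def test_requires_minimum_randomizations(self, small_bundle):
        with pytest.raises(ValueError):
            region_test("U" * 30, small_bundle.true_peak_regions(),
                        small_bundle.genome, 5, TriplexParams())

    def test_promoter_test_separates_target_genes(self, small_bundle):
        b = small_bundle
        rna = mask_rna(b.lncrna, b.profile)
        res = promoter_test(rna, b.manifest["tts_genes"], b.genes, b.genome)
        assert res["target"]["percent"] > res["non_target"]["percent"]
        assert res["p"] < 0.05

    def test_promoter_test_empty_list_error(self, small_bundle):
        with pytest.raises(ValueError):
            promoter_test("U" * 30, [], small_bundle.genes,
                          small_bundle.genome)
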