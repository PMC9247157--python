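"""The synthetic generator: determinism, planted-truth audits, feasibility."""

import hashlib
import os

import numpy as np
import pytest

from chirplex.annotate import RegionScheme
from chirplex.synth import (PlantedDBD, SyntheticConfig, generate_bundle,
                            perfect_tts_sequence, plant_tts, scrub_tracts)
from chirplex.triplex import TriplexParams, find_tts, score_window

from conftest import small_config


def _tree_hash(d):
    h = hashlib.sha256()
    for root, _, files in sorted(os.walk(d)):
        for f in sorted(files):
            h.update(f.encode())
            h.update(open(os.path.join(root, f), "rb").read())
    return h.hexdigest()


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticConfig(tts_target_fraction=1.5)

    def test_dbd_outside_lncrna(self):
        with pytest.raises(ValueError):
            SyntheticConfig(lncrna_length=150,
                            planted_dbds=[PlantedDBD(119, 196)])

    def test_more_tts_than_promoters(self):
        with pytest.raises(ValueError, match="promoters|budget"):
            generate_bundle(small_config(0, n_genes=2,
                                         tts_target_fraction=1.0))


class TestPlantTts:
    def test_poly_u_pyrimidine_motif(self):
        rng = np.random.default_rng(0)
        seq, (s, e) = plant_tts("T" * 60, "U" * 15, "pyrimidine_parallel",
                                0, offset=10, rng=rng)
        assert seq[s:e] == "A" * 15
        assert score_window("U" * 15, seq[s:e], "pyrimidine_parallel") == 0

    def test_poly_g_purine_motif(self):
        rng = np.random.default_rng(0)
        seq, (s, e) = plant_tts("T" * 60, "G" * 15, "purine_antiparallel",
                                0, offset=5, rng=rng)
        assert seq[s:e] == "G" * 15

    def test_exact_error_count_verified_by_scorer(self):
        rng = np.random.default_rng(1)
        for errors in (0, 1, 2, 3):
            rna = "".join(rng.choice(list("UC"), size=20))
            seq, (s, e) = plant_tts("T" * 80, rna, "pyrimidine_parallel",
                                    errors, offset=15, rng=rng)
            assert score_window(rna, seq[s:e], "pyrimidine_parallel") == errors

    def test_antiparallel_orientation(self):
        rng = np.random.default_rng(2)
        rna = "".join(rng.choice(list("UG"), size=20))
        seq, (s, e) = plant_tts("T" * 80, rna, "GT_antiparallel", 0,
                                offset=15, rng=rng)
        assert score_window(rna, seq[s:e], "GT_antiparallel") == 0

    def test_incompatible_base_budget(self):
        with pytest.raises(ValueError, match="mismatch"):
            plant_tts("T" * 60, "A" * 15, "pyrimidine_parallel", 0, offset=5)

    def test_planted_tract_is_a_tts(self):
        rng = np.random.default_rng(3)
        rna = "".join(rng.choice(list("UG"), size=25))
        seq, (s, e) = plant_tts("T" * 80, rna, "GT_parallel", 0, offset=20,
                                rng=rng)
        tracts = find_tts(seq.replace("U", "T"))
        assert any(t.start <= s and e <= t.end and t.purine_strand == "+"
                   for t in tracts)


class TestScrub:
    def test_no_qualifying_tract_after_scrub(self):
        rng = np.random.default_rng(4)
        codes = scrub_tracts(rng.integers(0, 4, size=30_000), rng)
        seq = "".join("ACGT"[c] for c in codes)
        step, block = 1_900, 2_000
        for s in range(0, len(seq), step):
            assert find_tts(seq[s:s + block]) == []


class TestGenerateBundle:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(n_chroms=1, chrom_length=120_000, n_genes=8,
                   peaks_per_replicate=20, n_noise_peaks=5,
                   tts_target_fraction=0.25)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_bundle(SyntheticConfig(seed=9, **cfg)).write(str(a))
        generate_bundle(SyntheticConfig(seed=9, **cfg)).write(str(b))
        assert _tree_hash(str(a)) == _tree_hash(str(b))
        c = tmp_path / "c"
        generate_bundle(SyntheticConfig(seed=10, **cfg)).write(str(c))
        assert _tree_hash(str(a)) != _tree_hash(str(c))

    def test_no_genes_bundle(self):
        b = generate_bundle(SyntheticConfig(
            seed=1, n_genes=0, tts_target_fraction=0.0, chrom_length=150_000,
            peaks_per_replicate=20, n_noise_peaks=5))
        assert b.genes == []
        assert all(not p["is_proximal"] for p in b.manifest["true_peaks"])

    def test_planted_tts_inside_its_region1_window(self, small_bundle):
        scheme = RegionScheme()
        by_id = {g.gene_id: g for g in small_bundle.genes}
        for rec in small_bundle.manifest["planted_tts"]:
            gene = by_id[rec["gene"]]
            lo, hi = scheme.window(gene, scheme.region1)
            assert lo <= rec["start"] < rec["end"] <= hi
            assert rec["chrom"] == gene.chrom

    def test_planted_tts_satisfies_motif_rules(self, small_bundle):
        b = small_bundle
        rna = b.lncrna.sequence
        for rec in b.manifest["planted_tts"]:
            chrom = b.genome[rec["chrom"]]
            core = chrom[rec["start"]:rec["end"]]
            purine = core if rec["purine_strand"] == "+" else \
                core.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            window = rna[rec["rna_start"] - 1:rec["rna_end"]]
            assert score_window(window, purine, rec["motif"]) == rec["errors"]
            # and it is detectable as a TTS
            assert len(find_tts(purine)) == 1

    def test_realized_proximal_fraction_within_tolerance(self, small_bundle):
        m = small_bundle.manifest
        assert abs(m["realized_proximal_fraction"]
                   - small_bundle.config.proximal_fraction) < 0.01

    def test_profile_keeps_planted_dbds_accessible(self, small_bundle):
        prof = small_bundle.profile
        for d in small_bundle.config.planted_dbds:
            assert prof[d.start - 1:d.end].min() >= 0.9

    def test_replicates_cover_true_peaks_with_jitter(self, small_bundle):
        b = small_bundle
        j = b.config.replicate_jitter
        for rep in b.replicate_peaks:
            names = {iv.name.rsplit("_rep", 1)[0] for iv in rep
                     if not iv.name.startswith("noise")}
            assert names == {p["name"] for p in b.manifest["true_peaks"]}
        truth = {p["name"]: p for p in b.manifest["true_peaks"]}
        for rep in b.replicate_peaks:
            for iv in rep:
                if iv.name.startswith("noise"):
                    continue
                t = truth[iv.name.rsplit("_rep", 1)[0]]
                assert abs(iv.start - t["start"]) <= j
                assert abs(iv.end - t["end"]) <= j

    def test_noise_is_replicate_private(self, small_bundle):
        """Noise peaks from different replicates never overlap after the
        consensus extension."""
        ext = 500
        spans = []
        for r, rep in enumerate(small_bundle.replicate_peaks):
            for i, iv in enumerate(rep):
                if iv.name.startswith("noise"):
                    c = rep.records[i].center
                    spans.append((r, iv.chrom, c - ext, c + ext))
        for i, (r1, c1, s1, e1) in enumerate(spans):
            for r2, c2, s2, e2 in spans[i + 1:]:
                if r1 != r2 and c1 == c2:
                    assert e1 <= s2 or e2 <= s1

    def test_manifest_counts_consistent(self, small_bundle):
        m = small_bundle.manifest
        cfg = small_bundle.config
        assert len(m["planted_tts"]) == cfg.n_tts_genes
        assert len(m["triplex_peaks"]) == cfg.n_tts_genes
        assert len(m["true_peaks"]) == cfg.peaks_per_replicate


class TestPerfectTtsSequence:
    def test_gt_mapping(self):
        pur, inherent = perfect_tts_sequence("UGUG", "GT_parallel")
        assert pur == "AGAG" and inherent == []

    def test_incompatible_positions_reported(self):
        pur, inherent = perfect_tts_sequence("UAUG", "GT_parallel")
        assert inherent == [1]

    def test_antiparallel_reverses(self):
        pur, _ = perfect_tts_sequence("UUG", "GT_antiparallel")
        assert pur == "GAA"
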