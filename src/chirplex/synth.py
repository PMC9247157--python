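"""Seeded synthetic fixture bundles with planted ground truth.

The generator emulates the inputs of a lncRNA ChIRP-seq triplex study so
that every downstream stage — consensus peaks, TSS annotation, triplex
search, enrichment, co-occurrence — can be exercised and scored against a
known truth without any download:

* a small multi-chromosome genome, i.i.d. ACGT but *scrubbed* of purine
  tracts that would qualify as triplex target sites, so the null is clean
  and every recovered site is a planted one;
* genes on regular slots with strand, TSS, exon/UTR sub-annotations;
* a lncRNA carrying planted triplex-forming domains (GU-rich, GT-motif by
  default) at configurable 1-based coordinates, plus a single-strandedness
  profile that keeps planted domains accessible (>= 0.9) and their
  immediate flanks paired (< 0.1), mirroring a structured transcript;
* purine-tract target sites (TTS) written into promoter region-1 windows of
  a configurable fraction of genes, each flanked by short pyrimidine runs
  so predicted hits have crisp boundaries, with an Alu-like element at a
  fixed edge-to-edge distance;
* three (configurable) replicate narrowPeak sets: shared true peaks with
  coordinate jitter, plus replicate-private noise peaks placed on
  replicate-exclusive stripes so they can never co-occur across replicates;
* histone-mark tracks whose presence at a peak depends on the peak's
  triplex status through a configurable odds parameter;
* per-gene expression fold changes coupled to triplex+Alu status, for the
  ranked-bin trend analysis.

Everything derives from one ``numpy`` Generator seeded by the config, so a
fixed seed gives byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import RegionScheme
from .intervals import GenomicInterval, NarrowPeakRecord, RegionSet
from .io import (GeneRecord, SequenceRecord, write_accessibility_profile,
                 write_fasta, write_genes, write_region_file)
from .triplex import ANTIPARALLEL_MOTIFS, MOTIF_TABLES, revcomp

_BASES = np.array(["A", "C", "G", "T"])

# RNA base -> purine-strand partner, per motif (perfect Hoogsteen triplet)
_PARTNER: Dict[str, Dict[str, str]] = {
    "pyrimidine_parallel": {"U": "A", "C": "G"},
    "purine_antiparallel": {"A": "A", "G": "G"},
    "GT_parallel": {"U": "A", "G": "G"},
    "GT_antiparallel": {"U": "A", "G": "G"},
}

TTS_FLANK = 10  # pyrimidine bases written on each side of a planted tract


@dataclass
class PlantedDBD:
    """A triplex-forming domain to plant in the lncRNA (1-based inclusive)."""

    start: int
    end: int
    motif: str = "GT_parallel"
    tts_len_range: Tuple[int, int] = (20, 40)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid DBD interval")
        if self.motif not in MOTIF_TABLES:
            raise ValueError(f"unknown motif {self.motif!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _default_dbds() -> List[PlantedDBD]:
    return [
        PlantedDBD(119, 196, "GT_parallel", (20, 40)),
        PlantedDBD(47, 70, "GT_parallel", (15, 16)),
    ]


def _default_marks() -> List[Tuple[str, float]]:
    return [("H3K4me1", 5.0), ("H3K27me3", 0.2)]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    # 30 genes per megabase-scale chromosome puts the chance that a random
    # 775-bp region touches a proximal window near the 8% background rate
    chrom_length: int = 1_040_000
    n_genes: int = 60
    gene_body_length: int = 1000
    lncrna_length: int = 2000
    planted_dbds: List[PlantedDBD] = field(default_factory=_default_dbds)
    decoy_tract: Optional[PlantedDBD] = None
    tts_target_fraction: float = 0.4
    tts_errors: int = 0
    alu_promoter_fraction: float = 0.25
    alu_background_fraction: float = 0.10
    alu_at_triplex: float = 0.9
    alu_consensus_length: int = 300
    alu_tts_gap: int = 150
    n_replicates: int = 3
    peaks_per_replicate: int = 300
    n_noise_peaks: int = 50
    proximal_fraction: float = 0.1023
    background_proximal_fraction: float = 0.0802
    replicate_jitter: int = 50
    detect_prob: float = 1.0
    peak_length_mean: int = 775
    peak_length_sd: int = 100
    min_peak_spacing: int = 2600
    mark_tracks: List[Tuple[str, float]] = field(default_factory=_default_marks)
    mark_base_rate: float = 0.3
    fc_trend_strength: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tts_target_fraction", "alu_promoter_fraction",
                     "alu_background_fraction", "alu_at_triplex",
                     "proximal_fraction", "background_proximal_fraction",
                     "detect_prob", "mark_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for dbd in self.planted_dbds:
            if dbd.end > self.lncrna_length:
                raise ValueError("planted DBD outside lncRNA")
        if self.n_genes > 0 and self.n_chroms > 0:
            per = -(-self.n_genes // self.n_chroms)
            if per > 0 and self.chrom_length // per < 10_000:
                raise ValueError("chromosomes too short for gene slots "
                                 "(need >= 10 kb per gene)")

    @property
    def n_tts_genes(self) -> int:
        return int(round(self.tts_target_fraction * self.n_genes))

    @property
    def n_proximal_peaks(self) -> int:
        return int(round(self.proximal_fraction * self.peaks_per_replicate))


@dataclass
class SyntheticBundle:
    """The complete fixture set plus its generating config and ground truth."""

    config: SyntheticConfig
    genome: Dict[str, str]
    genes: List[GeneRecord]
    exons: RegionSet
    utr5: RegionSet
    utr3: RegionSet
    alu: RegionSet
    replicate_peaks: List[RegionSet]
    lncrna: SequenceRecord
    profile: np.ndarray
    marks: Dict[str, RegionSet]
    fold_changes: Dict[str, float]
    manifest: dict

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def true_peak_regions(self) -> RegionSet:
        ivs = [GenomicInterval(p["chrom"], p["start"], p["end"],
                               name=p["name"])
               for p in self.manifest["true_peaks"]]
        return RegionSet("true_peaks", ivs)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(
            [SequenceRecord(c, s) for c, s in self.genome.items()],
            os.path.join(outdir, "genome.fa"))
        write_fasta([self.lncrna], os.path.join(outdir, "lncrna.fa"))
        write_genes(self.genes, os.path.join(outdir, "genes.bed"))
        for name, rs in (("exons", self.exons), ("utr5", self.utr5),
                         ("utr3", self.utr3), ("alu", self.alu)):
            write_region_file(rs, os.path.join(outdir, f"{name}.bed"))
        for i, rs in enumerate(self.replicate_peaks, start=1):
            write_region_file(rs, os.path.join(outdir, f"rep{i}.narrowPeak"),
                              "narrowPeak")
        write_accessibility_profile(
            self.profile, os.path.join(outdir, "accessibility.tsv"))
        marks_dir = os.path.join(outdir, "marks")
        os.makedirs(marks_dir, exist_ok=True)
        for name, rs in self.marks.items():
            write_region_file(rs, os.path.join(marks_dir, f"{name}.bed"))
        with open(os.path.join(outdir, "fold_changes.tsv"), "w") as fh:
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{self.fold_changes[g.gene_id]:.6f}\n")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# genome scrubbing

# Window screens that together exclude every purine (or pyrimidine) tract of
# length >= 15 with same-class fraction >= 0.8.  With all 15-windows capped
# at 10 same-class bases, a counting argument over 15-base chunks shows any
# residual qualifying tract must be 25-29 bp long (two dense runs bridged by
# a sparse gap); the second family of screens removes exactly those.
_SCREENS: List[Tuple[int, int]] = [(15, 11)] + [
    (w, -(-4 * w // 5)) for w in range(25, 30)
]


def _class_counts(is_pur: np.ndarray, w: int) -> np.ndarray:
    return np.convolve(is_pur.astype(np.int32), np.ones(w, dtype=np.int32),
                       mode="valid")


def scrub_tracts(codes: np.ndarray, rng: np.random.Generator,
                 max_iter: int = 60) -> np.ndarray:
    """Remove all TTS-qualifying tracts (both strands) from a base-code array.

    ``codes`` holds 0..3 for A,C,G,T.  Spans covered by offending windows
    are rewritten with a parity-alternating purine/pyrimidine pattern
    (random base identity within each class), which is offense-free by
    construction; iteration cleans up patch boundaries.
    """
    codes = codes.copy()
    n = codes.size
    for _ in range(max_iter):
        is_pur = (codes == 0) | (codes == 2)
        flagged = np.zeros(n, dtype=bool)
        hit = False
        for w, t in _SCREENS:
            if n < w:
                continue
            counts = _class_counts(is_pur, w)
            bad = (counts >= t) | (counts <= w - t)
            for s in np.flatnonzero(bad):
                flagged[s:s + w] = True
                hit = True
        if not hit:
            return codes
        # rewrite each flagged run with alternating classes (global parity)
        d = np.diff(flagged.astype(np.int8), prepend=0, append=0)
        for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            pos = np.arange(a, b)
            pur = rng.choice([0, 2], size=b - a)
            pyr = rng.choice([1, 3], size=b - a)
            codes[a:b] = np.where(pos % 2 == 0, pur, pyr)
    raise RuntimeError("tract scrubbing did not converge")


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _alu_consensus(length: int) -> str:
    """Fixed synthetic Alu-like consensus (deterministic, tract-free)."""
    rng = np.random.default_rng(987654321)
    codes = scrub_tracts(rng.integers(0, 4, size=length), rng)
    return _codes_to_seq(codes)


# ---------------------------------------------------------------------------
# planting

def perfect_tts_sequence(dbd_rna_seq: str, motif: str) -> Tuple[str, List[int]]:
    """Purine-strand sequence perfectly pairing an RNA window under a motif.

    RNA bases with no partner in the motif's triplet table are written as a
    purine that mismatches (an unavoidable error); their positions (relative
    to the returned purine strand, 5'->3') are returned alongside.
    """
    partner = _PARTNER[motif]
    out, inherent = [], []
    for r in dbd_rna_seq:
        if r in partner:
            out.append(partner[r])
        else:
            out.append("A")  # any purine mismatches an incompatible base
            inherent.append(len(out) - 1)
    if motif in ANTIPARALLEL_MOTIFS:
        n = len(out)
        inherent = [n - 1 - i for i in inherent]
        out = out[::-1]
    return "".join(out), sorted(inherent)


def plant_tts(promoter_seq: str, dbd_rna_seq: str, motif: str,
              errors: int = 0, offset: Optional[int] = None,
              rng: Optional[np.random.Generator] = None,
              flank: int = TTS_FLANK) -> Tuple[str, Tuple[int, int]]:
    """Write a triplex target site for an RNA window into a promoter sequence.

    The planted duplex window, scored against ``dbd_rna_seq`` under
    ``motif``, carries exactly ``errors`` mismatches (raises when the RNA
    contains more motif-incompatible bases than the error budget).  The
    tract is written on the plus strand with ``flank`` pyrimidine (C) bases
    on each side so that it forms a single crisp target site.  Returns the
    mutated promoter sequence and the (start, end) 0-based half-open
    interval of the tract core.
    """
    from .triplex import TriplexParams  # local import to avoid cycle at load

    rng = rng or np.random.default_rng(0)
    rna = dbd_rna_seq.upper().replace("T", "U")
    if len(rna) < TriplexParams().min_length:
        raise ValueError("RNA window shorter than the minimum triplex length")
    purine, inherent = perfect_tts_sequence(rna, motif)
    if len(inherent) > errors:
        raise ValueError(
            f"RNA window needs {len(inherent)} unavoidable mismatches under "
            f"{motif}, more than the requested {errors}")
    extra = errors - len(inherent)
    free = [i for i in range(len(purine)) if i not in inherent]
    arr = list(purine)
    for i in rng.choice(len(free), size=extra, replace=False) if extra else []:
        pos = free[int(i)]
        arr[pos] = "A" if arr[pos] == "G" else "G"  # purine that mismatches
    tract = "".join(arr)
    block = "C" * flank + tract + "C" * flank
    L = len(block)
    if L > len(promoter_seq):
        raise ValueError("promoter too short for the planted tract")
    if offset is None:
        offset = int(rng.integers(0, len(promoter_seq) - L + 1))
    if offset < 0 or offset + L > len(promoter_seq):
        raise ValueError("offset places the tract outside the promoter")
    new_seq = promoter_seq[:offset] + block + promoter_seq[offset + L:]
    return new_seq, (offset + flank, offset + flank + len(tract))


def _write_block(chrom_codes: np.ndarray, start: int, block: str) -> None:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    chrom_codes[start:start + len(block)] = [idx[b] for b in block]


# ---------------------------------------------------------------------------
# bundle generation

def _make_lncrna(cfg: SyntheticConfig, rng: np.random.Generator
                 ) -> Tuple[str, np.ndarray]:
    """lncRNA sequence with planted domains + structured accessibility."""
    bases = np.array(["A", "C", "G", "U"])
    seq = list(rng.choice(bases, size=cfg.lncrna_length))
    planted = list(cfg.planted_dbds)
    if cfg.decoy_tract is not None:
        planted.append(cfg.decoy_tract)
    for dbd in planted:
        for i in range(dbd.start - 1, dbd.end):
            seq[i] = "G" if rng.uniform() < 0.4 else "U"
    # block-structured profile: alternating paired helices and open loops
    profile = np.empty(cfg.lncrna_length)
    pos, paired = 0, bool(rng.integers(0, 2))
    while pos < cfg.lncrna_length:
        ln = int(rng.integers(5, 13) if paired else rng.integers(8, 25))
        val = rng.uniform(0.0, 0.08) if paired else rng.uniform(0.25, 1.0)
        profile[pos:pos + ln] = val
        pos += ln
        paired = not paired
    flank = 12
    for dbd in cfg.planted_dbds:
        s, e = dbd.start - 1, dbd.end
        profile[s:e] = rng.uniform(0.9, 1.0, size=e - s)
        profile[max(0, s - flank):s] = rng.uniform(0.0, 0.08,
                                                   size=s - max(0, s - flank))
        profile[e:e + flank] = rng.uniform(
            0.0, 0.08, size=min(cfg.lncrna_length, e + flank) - e)
    if cfg.decoy_tract is not None:
        d = cfg.decoy_tract
        profile[d.start - 1:d.end] = rng.uniform(0.0, 0.08,
                                                 size=d.end - d.start + 1)
    return "".join(seq), profile


def _make_genes(cfg: SyntheticConfig, rng: np.random.Generator,
                chrom_names: Sequence[str]):
    genes: List[GeneRecord] = []
    exons, u5, u3 = [], [], []
    if cfg.n_genes == 0:
        return genes, RegionSet("exons"), RegionSet("utr5"), RegionSet("utr3")
    per = -(-cfg.n_genes // cfg.n_chroms)
    body = cfg.gene_body_length
    gi = 0
    for chrom in chrom_names:
        slot = cfg.chrom_length // per
        for si in range(per):
            if gi >= cfg.n_genes:
                break
            slot_start = si * slot
            strand = "+" if rng.uniform() < 0.5 else "-"
            off = int(rng.integers(3000, slot - 3000 - body + 1))
            if strand == "+":
                tss = slot_start + off
                gene_end = tss + body - 1
                left, right = tss, gene_end + 1
            else:
                tss = slot_start + off + body - 1
                gene_end = slot_start + off
                left, right = gene_end, tss + 1
            gid = f"gene{gi + 1:03d}"
            genes.append(GeneRecord(gid, chrom, strand, tss, gene_end))
            # two 300-bp terminal exons; UTRs are the outer 100 bp
            exons.append(GenomicInterval(chrom, left, left + 300, strand, gid))
            exons.append(GenomicInterval(chrom, right - 300, right, strand, gid))
            if strand == "+":
                u5.append(GenomicInterval(chrom, left, left + 100, strand, gid))
                u3.append(GenomicInterval(chrom, right - 100, right, strand, gid))
            else:
                u5.append(GenomicInterval(chrom, right - 100, right, strand, gid))
                u3.append(GenomicInterval(chrom, left, left + 100, strand, gid))
            gi += 1
    return (genes, RegionSet("exons", exons), RegionSet("utr5", u5),
            RegionSet("utr3", u3))


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full fixture bundle for a config (deterministic in seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scheme = RegionScheme()

    lnc_seq, profile = _make_lncrna(cfg, rng)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    codes: Dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        codes[chrom] = scrub_tracts(
            rng.integers(0, 4, size=cfg.chrom_length), rng)

    genes, exons, utr5, utr3 = _make_genes(cfg, rng, chrom_names)

    # --- choose triplex target genes and plant tracts -----------------------
    n_tts = cfg.n_tts_genes
    if n_tts > len(genes) and n_tts > 0:
        raise ValueError("more planted TTS than promoters available")
    if n_tts > cfg.n_proximal_peaks and cfg.peaks_per_replicate > 0:
        raise ValueError("proximal peak budget smaller than planted TTS genes")
    order = rng.permutation(max(len(genes), 1))
    tts_gene_idx = sorted(int(i) for i in order[:n_tts]) if genes else []
    planted = list(cfg.planted_dbds)
    anchor_count = {i: 0 for i in range(len(planted))}
    tts_records: List[dict] = []
    alu_records: List[GenomicInterval] = []
    alu_seq = _alu_consensus(cfg.alu_consensus_length)
    alu_genes: set = set()

    for n, gidx in enumerate(tts_gene_idx):
        gene = genes[gidx]
        dbd_i = n % len(planted) if planted else 0
        dbd = planted[dbd_i]
        lo, hi = dbd.tts_len_range
        core_len = int(rng.integers(lo, hi + 1))
        core_len = min(core_len, dbd.length)
        k = anchor_count[dbd_i]
        anchor_count[dbd_i] += 1
        if k == 0:
            rs = dbd.start                      # left-anchored
        elif k == 1:
            rs = dbd.end - core_len + 1         # right-anchored
        else:
            rs = dbd.start + int(rng.integers(0, dbd.length - core_len + 1))
        re_ = rs + core_len - 1
        rna_core = lnc_seq[rs - 1:re_]
        purine, inherent = perfect_tts_sequence(rna_core, dbd.motif)
        if len(inherent) > cfg.tts_errors:
            raise ValueError("planted DBD incompatible with its motif")
        win_lo, win_hi = scheme.window(gene, scheme.region1)
        block = "C" * TTS_FLANK + purine + "C" * TTS_FLANK
        place = win_lo + 20 + int(rng.integers(0, 11))
        strand = "+" if rng.uniform() < 0.5 else "-"
        written = block if strand == "+" else revcomp(block)
        _write_block(codes[gene.chrom], place, written)
        core_s = place + TTS_FLANK  # flanks are symmetric on both strands
        core_e = core_s + len(purine)
        tts_records.append({
            "gene": gene.gene_id, "chrom": gene.chrom,
            "start": int(core_s), "end": int(core_e),
            "purine_strand": strand, "dbd_index": dbd_i,
            "rna_start": int(rs), "rna_end": int(re_),
            "motif": dbd.motif, "errors": int(cfg.tts_errors),
        })
        # decoy TTS so an unmasked search would find the decoy TFO
        if cfg.decoy_tract is not None:
            d = cfg.decoy_tract
            dlo, dhi = d.tts_len_range
            dlen = min(int(rng.integers(dlo, dhi + 1)), d.length)
            drs = d.start + int(rng.integers(0, d.length - dlen + 1))
            dcore = lnc_seq[drs - 1:drs - 1 + dlen]
            dpur, dinh = perfect_tts_sequence(dcore, d.motif)
            if not dinh:
                dblock = "C" * TTS_FLANK + dpur + "C" * TTS_FLANK
                dplace = win_lo + 620 + int(rng.integers(0, 11))
                _write_block(codes[gene.chrom], dplace, dblock)
        # Alu near the tract (most triplex-forming peaks carry one close by)
        if rng.uniform() < cfg.alu_at_triplex:
            a_start = core_e + cfg.alu_tts_gap
            _write_block(codes[gene.chrom], a_start, alu_seq)
            alu_records.append(GenomicInterval(
                gene.chrom, a_start, a_start + len(alu_seq),
                name=f"alu_{gene.gene_id}"))
            alu_genes.add(gene.gene_id)

    # Alu elements in promoters of non-target genes
    tts_set = set(tts_gene_idx)
    for gidx, gene in enumerate(genes):
        if gidx in tts_set:
            continue
        if rng.uniform() < cfg.alu_promoter_fraction:
            win_lo, win_hi = scheme.window(gene, scheme.proximal)
            a_start = win_lo + int(rng.integers(
                0, win_hi - win_lo - len(alu_seq) + 1))
            _write_block(codes[gene.chrom], a_start, alu_seq)
            alu_records.append(GenomicInterval(
                gene.chrom, a_start, a_start + len(alu_seq),
                name=f"alu_{gene.gene_id}"))
            alu_genes.add(gene.gene_id)

    # --- true peaks ---------------------------------------------------------
    true_peaks: List[dict] = []
    centers_by_chrom: Dict[str, List[int]] = {c: [] for c in chrom_names}

    def spacing_ok(chrom: str, center: int) -> bool:
        return all(abs(center - c) >= cfg.min_peak_spacing
                   for c in centers_by_chrom[chrom])

    def peak_len() -> int:
        return max(200, int(round(rng.normal(cfg.peak_length_mean,
                                             cfg.peak_length_sd))))

    for rec in tts_records:
        gene = next(g for g in genes if g.gene_id == rec["gene"])
        alu_end = rec["end"] + cfg.alu_tts_gap + len(alu_seq)
        span = alu_end - rec["start"]
        L = max(peak_len(), span + 60)
        center = (rec["start"] + alu_end) // 2 + int(rng.integers(-30, 31))
        s = center - L // 2
        true_peaks.append({
            "name": f"peak{len(true_peaks) + 1:04d}", "chrom": rec["chrom"],
            "start": int(s), "end": int(s + L), "center": int(center),
            "is_proximal": True, "is_triplex": True, "gene": rec["gene"],
        })
        centers_by_chrom[rec["chrom"]].append(center)

    n_extra_prox = (cfg.n_proximal_peaks - len(tts_records)) if genes else 0
    non_tts_genes = [g for i, g in enumerate(genes) if i not in tts_set]
    if n_extra_prox > len(non_tts_genes):
        raise ValueError("not enough genes for the proximal peak budget")
    extra_idx = (rng.choice(len(non_tts_genes), size=n_extra_prox,
                            replace=False) if n_extra_prox > 0 else [])
    for i in sorted(int(j) for j in np.atleast_1d(extra_idx)):
        gene = non_tts_genes[i]
        win_lo, win_hi = scheme.window(gene, scheme.proximal)
        for _ in range(200):
            center = int(rng.integers(win_lo, win_hi))
            if spacing_ok(gene.chrom, center):
                break
        else:
            raise RuntimeError("could not place proximal peak")
        L = peak_len()
        s = center - L // 2
        true_peaks.append({
            "name": f"peak{len(true_peaks) + 1:04d}", "chrom": gene.chrom,
            "start": int(s), "end": int(s + L), "center": int(center),
            "is_proximal": True, "is_triplex": False, "gene": gene.gene_id,
        })
        centers_by_chrom[gene.chrom].append(center)

    prox_windows: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    for g in genes:
        lo, hi = scheme.window(g, scheme.proximal)
        prox_windows[g.chrom].append((lo, hi))
    n_background = cfg.peaks_per_replicate - len(true_peaks)
    sizes = np.array([cfg.chrom_length] * cfg.n_chroms, dtype=float)
    for _ in range(n_background):
        for _try in range(2000):
            ci = int(rng.choice(cfg.n_chroms, p=sizes / sizes.sum()))
            chrom = chrom_names[ci]
            center = int(rng.integers(1000, cfg.chrom_length - 1000))
            if not spacing_ok(chrom, center):
                continue
            # keep the whole peak span clear of proximal windows so the
            # realized proximal fraction equals the configured budget
            if any(lo - 800 <= center < hi + 800
                   for lo, hi in prox_windows[chrom]):
                continue
            break
        else:
            raise RuntimeError("could not place background peak "
                               "(genome too crowded)")
        L = peak_len()
        s = max(0, center - L // 2)
        rec = {
            "name": f"peak{len(true_peaks) + 1:04d}", "chrom": chrom,
            "start": int(s), "end": int(s + L), "center": int(center),
            "is_proximal": False, "is_triplex": False, "gene": "",
        }
        if rng.uniform() < cfg.alu_background_fraction:
            a_start = center - 150 + int(rng.integers(-50, 51))
            _write_block(codes[chrom], a_start, alu_seq)
            alu_records.append(GenomicInterval(
                chrom, a_start, a_start + len(alu_seq),
                name=f"alu_{rec['name']}"))
        true_peaks.append(rec)
        centers_by_chrom[chrom].append(center)

    # --- replicate narrowPeak sets -----------------------------------------
    replicate_sets = generate_replicate_peaks(cfg, true_peaks, rng)

    # --- histone-mark tracks -----------------------------------------------
    marks: Dict[str, RegionSet] = {}
    p0 = cfg.mark_base_rate
    for name, odds in cfg.mark_tracks:
        o0 = p0 / (1 - p0)
        p1 = odds * o0 / (1 + odds * o0)
        ivs = []
        for pk in true_peaks:
            p = p1 if pk["is_triplex"] else p0
            if rng.uniform() < p:
                a = pk["center"] - int(rng.integers(200, 601))
                b = pk["center"] + int(rng.integers(200, 601))
                ivs.append(GenomicInterval(pk["chrom"], max(0, a), b,
                                           name=f"{name}_{pk['name']}"))
        marks[name] = RegionSet(name, ivs)

    # --- fold changes coupled to triplex+Alu status -------------------------
    tts_gene_ids = {r["gene"] for r in tts_records}
    fold_changes: Dict[str, float] = {}
    for g in genes:
        mag = float(rng.exponential(1.0))
        if g.gene_id in tts_gene_ids and g.gene_id in alu_genes:
            mag += cfg.fc_trend_strength
        sign = -1.0 if rng.uniform() < 0.5 else 1.0
        fold_changes[g.gene_id] = sign * mag

    genome = {c: _codes_to_seq(codes[c]) for c in chrom_names}
    manifest = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "planted_dbds": [
            {"start": d.start, "end": d.end, "motif": d.motif}
            for d in cfg.planted_dbds],
        "planted_tts": tts_records,
        "alu": [{"chrom": a.chrom, "start": a.start, "end": a.end,
                 "name": a.name} for a in alu_records],
        "true_peaks": true_peaks,
        "triplex_peaks": [p["name"] for p in true_peaks if p["is_triplex"]],
        "tts_genes": sorted(tts_gene_ids),
        "alu_genes": sorted(alu_genes),
        "realized_proximal_fraction": (
            cfg.n_proximal_peaks / cfg.peaks_per_replicate
            if cfg.peaks_per_replicate else 0.0),
    }
    return SyntheticBundle(
        config=cfg, genome=genome, genes=genes, exons=exons, utr5=utr5,
        utr3=utr3, alu=RegionSet("alu", alu_records),
        replicate_peaks=replicate_sets,
        lncrna=SequenceRecord("lncRNA", lnc_seq, "RNA"),
        profile=profile, marks=marks, fold_changes=fold_changes,
        manifest=manifest)


def generate_replicate_peaks(cfg: SyntheticConfig, true_peaks: List[dict],
                             rng: np.random.Generator) -> List[RegionSet]:
    """Replicate narrowPeak sets: jittered true peaks + striped private noise.

    Every true peak enters each replicate independently with
    ``detect_prob``; replicate-private noise peaks are placed on stripes
    assigned exclusively to one replicate (with margins wider than the
    consensus extension), so noise can never be shared across replicates.
    """
    stripe = 3000
    sets: List[RegionSet] = []
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    for r in range(cfg.n_replicates):
        ivs, recs = [], []
        for pk in true_peaks:
            if rng.uniform() >= cfg.detect_prob:
                continue
            j = cfg.replicate_jitter
            ds = int(rng.integers(-j, j + 1)) if j else 0
            de = int(rng.integers(-j, j + 1)) if j else 0
            s = max(0, pk["start"] + ds)
            e = max(s + 100, pk["end"] + de)
            summit = min(max(pk["center"] + (int(rng.integers(-10, 11))
                                             if j else 0), s), e - 1)
            iv = GenomicInterval(pk["chrom"], s, e,
                                 name=f"{pk['name']}_rep{r + 1}")
            ivs.append(iv)
            recs.append(NarrowPeakRecord(iv, summit - s,
                                         float(np.round(rng.uniform(5, 50), 3)),
                                         float(np.round(rng.uniform(5, 90), 3)),
                                         float(np.round(rng.uniform(3, 60), 3))))
        n_stripes = cfg.chrom_length // stripe
        for k in range(cfg.n_noise_peaks):
            ci = int(rng.integers(0, cfg.n_chroms))
            own = [i for i in range(n_stripes)
                   if i % cfg.n_replicates == r]
            si = own[int(rng.integers(0, len(own)))]
            center = si * stripe + 600 + int(rng.integers(0, stripe - 1200))
            L = max(200, int(round(rng.normal(cfg.peak_length_mean,
                                              cfg.peak_length_sd))))
            s = max(0, center - L // 2)
            iv = GenomicInterval(chrom_names[ci], s, s + L,
                                 name=f"noise_rep{r + 1}_{k + 1}")
            ivs.append(iv)
            recs.append(NarrowPeakRecord(iv, center - s,
                                         float(np.round(rng.uniform(5, 20), 3)),
                                         float(np.round(rng.uniform(5, 30), 3)),
                                         float(np.round(rng.uniform(3, 20), 3))))
        rs = RegionSet(f"rep{r + 1}", ivs, records=recs).normalized()
        sets.append(rs)
    return sets


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    return d
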