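"""Hoogsteen-rule RNA:DNA triplex search.

A triplex forms when a single-stranded RNA stretch (the triplex-forming
oligonucleotide, TFO) lies in the major groove of duplex DNA along a
purine-rich tract (the triplex target site, TTS), pairing by Hoogsteen
bonds.  Four canonical binding motifs are modeled, each a per-position match
table between the RNA base and the base of the *purine strand* of the
duplex:

* ``pyrimidine_parallel``: U.A and C.G triplets, RNA parallel to the purine
  strand;
* ``purine_antiparallel``: A.A and G.G, RNA read 3'->5' against the purine
  strand;
* ``GT_parallel`` / ``GT_antiparallel``: G.G and U.A in either orientation.

The search is mismatch-only (no indels; triplex geometry disallows bulges at
this modeling level).  A hit is a maximal aligned window with length >=
``min_length`` and mismatch rate <= ``max_error_rate``; maximality means
extending the window by one position in either direction violates the rate
or runs off a sequence boundary.  A guanine-content filter on the TFO is
applied after maximality.  RNA bases predicted to be double-stranded
(probability of single-strandedness below ``ss_prob_threshold``) can be
masked out; masked bases are hard breaks, so masking can only remove hits.

Every match in every motif requires a purine on the purine strand, so a
window with mismatch rate <= e has purine fraction >= 1-e and lies inside a
maximal purine tract.  The scanner therefore first locates TTS tracts
(:func:`find_tts`) and aligns the RNA only against those, verifying each
candidate's maximality against the full region; the result is exactly
equivalent to the exhaustive all-offsets/all-windows scan (and is tested
against one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, RegionSet
from .io import SequenceRecord

MASK = "N"

MOTIF_TABLES: Dict[str, frozenset] = {
    "pyrimidine_parallel": frozenset({("U", "A"), ("C", "G")}),
    "purine_antiparallel": frozenset({("A", "A"), ("G", "G")}),
    "GT_parallel": frozenset({("G", "G"), ("U", "A")}),
    "GT_antiparallel": frozenset({("G", "G"), ("U", "A")}),
}
ANTIPARALLEL_MOTIFS = frozenset({"purine_antiparallel", "GT_antiparallel"})
ALL_MOTIFS = tuple(MOTIF_TABLES)

_COMPLEMENT = str.maketrans("ACGTNU", "TGCANA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _ratio(x: float) -> Fraction:
    """Exact rational for a user-supplied decimal rate (avoids 0.8*15 > 12)."""
    return Fraction(str(float(x)))


@dataclass
class TriplexParams:
    min_length: int = 15
    max_error_rate: float = 0.20
    min_guanine_rate: float = 0.10
    motifs: Tuple[str, ...] = ALL_MOTIFS
    merge_gap: int = 10
    ss_prob_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.min_length < 10:
            raise ValueError("min_length must be >= 10")
        for r in (self.max_error_rate, self.min_guanine_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        unknown = set(self.motifs) - set(ALL_MOTIFS)
        if unknown:
            raise ValueError(f"unknown motifs {sorted(unknown)}")


@dataclass
class TTS:
    """A maximal purine tract of duplex DNA (candidate triplex target site).

    Coordinates are 0-based half-open within the scanned window;
    ``purine_seq`` is the 5'->3' sequence of the purine strand.
    """

    start: int
    end: int
    purine_strand: str
    purine_seq: str


@dataclass
class TriplexHit:
    """One predicted triplex: an RNA window paired to a DNA duplex window.

    ``rna_start``/``rna_end`` are 1-based inclusive transcript coordinates
    (the reporting convention for RNA domains); ``dna`` is the genomic DBS
    interval, 0-based half-open, with strand = purine strand.
    """

    rna_start: int
    rna_end: int
    dna: GenomicInterval
    motif: str
    length: int
    mismatches: int
    region_name: str = ""

    @property
    def error_rate(self) -> float:
        return self.mismatches / self.length


@dataclass
class DBD:
    """A merged RNA-side domain supported by triplex hits (1-based inclusive)."""

    rna_start: int
    rna_end: int
    n_hits: int
    n_supporting_regions: int
    supporting_regions: frozenset = frozenset()

    def overlaps_rna(self, start: int, end: int) -> bool:
        return start <= self.rna_end and end >= self.rna_start


@dataclass
class RegionTestResult:
    """Observed vs randomized count of target regions carrying >= 1 DBS."""

    dbd: Optional[DBD]
    observed: int
    n_regions: int
    null_mean: float
    null_sd: float
    z: Optional[float]
    p: float


def mask_rna(rna, profile: np.ndarray, threshold: float = 0.10) -> str:
    """Replace bases with P(single-stranded) < threshold by the mask symbol."""
    seq = normalize_rna(rna.sequence if isinstance(rna, SequenceRecord) else rna)
    profile = np.asarray(profile, dtype=float)
    if profile.shape[0] != len(seq):
        raise ValueError(
            f"profile length {profile.shape[0]} != RNA length {len(seq)}"
        )
    chars = np.array(list(seq))
    chars[profile < threshold] = MASK
    return "".join(chars)


def _maximal_windows(good: np.ndarray, min_len: int, min_rate: Fraction
                     ) -> List[Tuple[int, int]]:
    """All maximal windows [i,j) of a boolean array with mean >= min_rate.

    Maximal: extending one step left or right violates the rate or the array
    bound.  Vectorized over all (i, j) pairs; arrays here are short (purine
    tracts, diagonals of small match matrices).
    """
    n = int(good.size)
    if n < min_len:
        return []
    num, den = min_rate.numerator, min_rate.denominator
    c = np.concatenate([[0], np.cumsum(good.astype(np.int64))])
    idx = np.arange(n + 1, dtype=np.int64)
    # score[i] = den*c[i] - num*i ; window [i,j) ok <=> score[j] >= score[i]
    score = den * c - num * idx
    big = np.int64(2 ** 62)
    # sentinels so the boundary cases fold into the same comparisons
    s_prev = np.concatenate([[big], score[:-1]])       # score[s-1], +inf at s=0
    s_next = np.concatenate([score[1:], [-big]])       # score[e+1], -inf at e=n
    e_idx = np.arange(min_len, n + 1)
    Se, SeN = score[e_idx], s_next[e_idx]
    out: List[Tuple[int, int]] = []
    for s0 in range(0, n - min_len + 1, 256):
        s_idx = np.arange(s0, min(s0 + 256, n - min_len + 1))
        Sv = score[s_idx][:, None]
        keep = ((e_idx[None, :] >= s_idx[:, None] + min_len)
                & (Se[None, :] >= Sv)
                & (Se[None, :] < s_prev[s_idx][:, None])
                & (SeN[None, :] < Sv))
        rows, cols = np.nonzero(keep)
        out.extend(zip((s_idx[rows]).tolist(), (e_idx[cols]).tolist()))
    return out


def find_tts(dna_window: str, params: TriplexParams = TriplexParams()
             ) -> List[TTS]:
    """Maximal purine tracts on either strand of a DNA window.

    A tract qualifies when its length is >= ``min_length`` and the purine
    fraction of one strand is >= 1 - ``max_error_rate``.  Minus-strand
    tracts are purine tracts of the reverse complement (pyrimidine tracts of
    the given sequence).
    """
    seq = dna_window.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("DNA window must contain only ACGT")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_pur = (arr == b"A") | (arr == b"G")
    min_rate = 1 - _ratio(params.max_error_rate)
    out: List[TTS] = []
    for s, e in _maximal_windows(is_pur, params.min_length, min_rate):
        out.append(TTS(s, e, "+", seq[s:e]))
    for s, e in _maximal_windows(~is_pur, params.min_length, min_rate):
        out.append(TTS(s, e, "-", revcomp(seq[s:e])))
    out.sort(key=lambda t: (t.start, t.end, t.purine_strand))
    return out


def score_window(rna_window: str, tts_purine_seq: str, motif: str) -> int:
    """Mismatch count of an RNA window against a purine-strand window.

    For antiparallel motifs the RNA is read 3'->5' against the purine strand
    (i.e. reversed before position-wise comparison).  A masked RNA base
    always mismatches.
    """
    if motif not in MOTIF_TABLES:
        raise ValueError(f"unknown motif {motif!r}")
    if len(rna_window) != len(tts_purine_seq):
        raise ValueError("windows must have equal length")
    rna = normalize_rna(rna_window)
    if motif in ANTIPARALLEL_MOTIFS:
        rna = rna[::-1]
    table = MOTIF_TABLES[motif]
    return sum(
        1 for r, d in zip(rna, tts_purine_seq.upper()) if (r, d) not in table
    )


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


def _match_vector(x: np.ndarray, y: np.ndarray, motif: str) -> np.ndarray:
    table = MOTIF_TABLES[motif]
    m = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=bool)
    for r, d in table:
        m |= (x == r.encode()) & (y == d.encode())
    return m


def _rna_segments(rna: str, min_length: int) -> List[Tuple[int, str]]:
    """Maximal unmasked runs of the RNA as (offset, subsequence), length >= min."""
    segs: List[Tuple[int, str]] = []
    start = None
    for i, ch in enumerate(rna + MASK):
        if ch not in "ACGU":
            if start is not None and i - start >= min_length:
                segs.append((start, rna[start:i]))
            start = None
        elif start is None:
            start = i
    return segs


def _guanine_ok(rna_window: str, params: TriplexParams) -> bool:
    r = _ratio(params.min_guanine_rate)
    return rna_window.count("G") * r.denominator >= r.numerator * len(rna_window)


def _scan_pair(X: np.ndarray, Y: np.ndarray, tract_lo: int, tract_hi: int,
               motif: str, min_len: int, min_rate: Fraction):
    """Maximal qualifying diagonal windows of X (RNA frame) vs Y (purine frame).

    Alignment pairs X[i] with Y[i - k]; the candidate search is restricted to
    Y positions inside [tract_lo, tract_hi) but maximality is verified against
    the full X and Y (a window flush with a tract edge may extend into an
    adjacent lower-purity stretch and still satisfy the rate; such a window
    belongs to a longer tract and is found there).  Yields
    (x_start, x_end, y_start, y_end, mismatches).
    """
    R, W = len(X), len(Y)
    table = MOTIF_TABLES[motif]
    num, den = min_rate.numerator, min_rate.denominator

    def match(i: int, j: int) -> bool:
        return (chr(X[i][0]), chr(Y[j][0])) in table

    # prescreen: a qualifying window carries >= ceil(rate*min_len) matches,
    # all on one diagonal; only diagonals reaching that total are enumerated
    M = _match_vector(X[:, None], Y[None, tract_lo:tract_hi], motif)
    ii, jj = np.nonzero(M)
    if ii.size == 0:
        return
    t_min = -(-num * min_len // den)
    diag_tot = np.bincount(ii - jj + (tract_hi - tract_lo) - 1)
    good_d = np.flatnonzero(diag_tot >= t_min) - (tract_hi - tract_lo) + 1
    ks = sorted(int(d) - tract_lo for d in good_d)
    for k in ks:
        if not (min_len - tract_hi <= k <= R - min_len - tract_lo):
            continue
        # X index range aligned against the tract on this diagonal
        lo = max(0, k + tract_lo)
        hi = min(R, k + tract_hi)
        if hi - lo < min_len:
            continue
        diag = _match_vector(X[lo:hi], Y[lo - k:hi - k], motif)
        cum = np.concatenate([[0], np.cumsum(diag)])
        for s, e in _maximal_windows(diag, min_len, min_rate):
            a, b = lo + s, lo + e
            matches = int(cum[e] - cum[s])
            length = e - s
            # re-check maximality against full X/Y bounds
            maximal = True
            for (xi, yj) in ((a - 1, a - 1 - k), (b, b - k)):
                if 0 <= xi < R and 0 <= yj < W:
                    m = matches + (1 if match(xi, yj) else 0)
                    if m * den >= num * (length + 1):
                        maximal = False
                        break
            if maximal:
                yield (a, b, a - k, b - k, length - matches)


def find_triplex_hits(rna: str, dna_regions: RegionSet, genome: Dict[str, str],
                      params: TriplexParams = TriplexParams(),
                      ) -> List[TriplexHit]:
    """All maximal triplex hits between an RNA and a set of genomic regions.

    ``rna`` may contain mask symbols (see :func:`mask_rna`); masked bases are
    excluded from the search.  ``genome`` maps chromosome name to sequence
    (plain strings; a dict of :class:`SequenceRecord` also works).
    """
    genome = {c: (s.sequence if isinstance(s, SequenceRecord) else s)
              for c, s in genome.items()}
    rna_n = normalize_rna(rna)
    hits: List[TriplexHit] = []
    if sum(c in "ACGU" for c in rna_n) < params.min_length:
        warnings.warn("RNA shorter than min_length; no triplex search possible")
        return hits
    segments = _rna_segments(rna_n, params.min_length)
    min_rate = 1 - _ratio(params.max_error_rate)
    for region in dna_regions:
        if region.chrom not in genome:
            raise KeyError(f"chromosome {region.chrom!r} absent from genome")
        chrom_seq = genome[region.chrom]
        if region.end > len(chrom_seq):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {len(chrom_seq)}"
            )
        window = chrom_seq[region.start:region.end].upper()
        W = len(window)
        tracts = find_tts(window, params)
        if not tracts:
            continue
        frames = {
            "+": _seq_array(window),
            "-": _seq_array(revcomp(window)),
        }
        # merge tracts into per-strand candidate zones (overlapping maximal
        # tracts share hit windows; scanning the union once is equivalent)
        raw_zones: Dict[str, List[Tuple[int, int]]] = {"+": [], "-": []}
        for tts in tracts:
            if tts.purine_strand == "+":
                raw_zones["+"].append((tts.start, tts.end))
            else:
                raw_zones["-"].append((W - tts.end, W - tts.start))
        zones: Dict[str, List[Tuple[int, int]]] = {"+": [], "-": []}
        for strand, zs in raw_zones.items():
            for lo_hi in sorted(zs):
                merged = zones[strand]
                if merged and lo_hi[0] <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], lo_hi[1]))
                else:
                    merged.append(lo_hi)
        seen = set()
        for strand in ("+", "-"):
            Y = frames[strand]
            for t_lo, t_hi in zones[strand]:
              for seg_off, seg in segments:
                for motif in params.motifs:
                    anti = motif in ANTIPARALLEL_MOTIFS
                    X = _seq_array(seg[::-1] if anti else seg)
                    for (xa, xb, ya, yb, mism) in _scan_pair(
                            X, Y, t_lo, t_hi, motif, params.min_length,
                            min_rate):
                        # RNA transcript coords (0-based half-open)
                        if anti:
                            rs, re_ = len(seg) - xb, len(seg) - xa
                        else:
                            rs, re_ = xa, xb
                        rs += seg_off
                        re_ += seg_off
                        # window coords of the DNA side
                        if strand == "+":
                            ws, we = ya, yb
                        else:
                            ws, we = W - yb, W - ya
                        # one record per physical triplex: identical windows
                        # found under several motifs (U.A is shared by the
                        # pyrimidine and GT tables) keep the first motif in
                        # priority order pyrimidine > purine > GT
                        key = (rs, re_, ws, we, strand, mism)
                        if key in seen:
                            continue
                        seen.add(key)
                        rna_win = rna_n[rs:re_]
                        if not _guanine_ok(rna_win, params):
                            continue
                        hits.append(TriplexHit(
                            rna_start=rs + 1, rna_end=re_,
                            dna=GenomicInterval(
                                region.chrom, region.start + ws,
                                region.start + we, strand,
                                name=region.name),
                            motif=motif, length=re_ - rs, mismatches=mism,
                            region_name=region.name,
                        ))
    hits.sort(key=lambda h: (h.region_name, h.dna.chrom, h.dna.start,
                             h.rna_start, h.motif, h.dna.strand))
    return hits


def merge_dbds(hits: Sequence[TriplexHit], merge_gap: int = 10) -> List[DBD]:
    """Merge hit TFO intervals closer than ``merge_gap`` nt into DBDs.

    Each DBD carries the number of hits and of distinct target regions
    supporting it.  Coordinates stay 1-based inclusive on the transcript.
    """
    if not hits:
        return []
    spans = sorted((h.rna_start, h.rna_end, h.region_name) for h in hits)
    groups: List[list] = []
    cur_start, cur_end, members = spans[0][0], spans[0][1], [spans[0]]
    for s, e, reg in spans[1:]:
        if s - cur_end - 1 < merge_gap:
            cur_end = max(cur_end, e)
            members.append((s, e, reg))
        else:
            groups.append([cur_start, cur_end, members])
            cur_start, cur_end, members = s, e, [(s, e, reg)]
    groups.append([cur_start, cur_end, members])
    out = []
    for start, end, mem in groups:
        regions = frozenset(m[2] for m in mem)
        out.append(DBD(start, end, len(mem), len(regions), regions))
    return out


def _regions_with_dbs(hits: Sequence[TriplexHit],
                      dbd: Optional[DBD] = None) -> set:
    """Distinct region names carrying >= 1 DBS (optionally for one DBD)."""
    out = set()
    for h in hits:
        if dbd is None or dbd.overlaps_rna(h.rna_start, h.rna_end):
            out.add(h.region_name)
    return out


def sample_matched_regions(rng: np.random.Generator, templates: RegionSet,
                           chrom_sizes: Dict[str, int],
                           background: Optional[RegionSet] = None) -> RegionSet:
    """Length-matched random regions: one per template interval.

    By default regions are drawn uniformly over genome coordinates (chromosome
    weighted by placeable positions); with ``background`` each template is
    matched to a random same-or-larger background interval and placed inside
    it.
    """
    ivs = []
    if background is not None:
        pool = list(background)
        for i, tmpl in enumerate(templates):
            L = len(tmpl)
            fits = [b for b in pool if len(b) >= L]
            if not fits:
                raise ValueError(f"no background interval can hold length {L}")
            b = fits[int(rng.integers(0, len(fits)))]
            s = int(rng.integers(b.start, b.end - L + 1))
            ivs.append(GenomicInterval(b.chrom, s, s + L, name=f"null{i + 1}"))
        return RegionSet("null", ivs)
    chroms = sorted(chrom_sizes)
    for i, tmpl in enumerate(templates):
        L = len(tmpl)
        fit = [c for c in chroms if chrom_sizes[c] >= L]
        if not fit:
            raise ValueError(f"no chromosome can hold length {L}")
        w = np.array([chrom_sizes[c] - L + 1 for c in fit], dtype=float)
        c = fit[int(rng.choice(len(fit), p=w / w.sum()))]
        s = int(rng.integers(0, chrom_sizes[c] - L + 1))
        ivs.append(GenomicInterval(c, s, s + L, name=f"null{i + 1}"))
    return RegionSet("null", ivs)


def region_test(rna: str, target_regions: RegionSet, genome: Dict[str, str],
                n_randomizations: int = 99,
                params: TriplexParams = TriplexParams(),
                seed: int = 0,
                background: Optional[RegionSet] = None,
                randomized_p: bool = False) -> List[RegionTestResult]:
    """Genomic region test: are target regions unusually triplex-prone?

    Counts target regions with >= 1 DBS, overall and per discovered DBD, and
    compares against ``n_randomizations`` draws of length-matched random
    regions.  Empirical p = (1 + #{null >= observed}) / (n + 1);
    z = (obs - mean_null) / sd_null (None when sd_null = 0).
    ``randomized_p`` breaks ties uniformly (exactly uniform under the null).
    """
    if n_randomizations < 19:
        raise ValueError("need n_randomizations >= 19")
    genome = {c: (s.sequence if isinstance(s, SequenceRecord) else s)
              for c, s in genome.items()}
    rng = np.random.default_rng(seed)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    obs_hits = find_triplex_hits(rna, target_regions, genome, params)
    dbds = merge_dbds(obs_hits, params.merge_gap)
    units: List[Optional[DBD]] = [None] + list(dbds)
    observed = [len(_regions_with_dbs(obs_hits, d)) for d in units]
    null_counts = np.zeros((n_randomizations, len(units)), dtype=int)
    for r in range(n_randomizations):
        rand_regions = sample_matched_regions(rng, target_regions, chrom_sizes,
                                              background)
        null_hits = find_triplex_hits(rna, rand_regions, genome, params)
        for ui, d in enumerate(units):
            null_counts[r, ui] = len(_regions_with_dbs(null_hits, d))
    results = []
    n = n_randomizations
    for ui, d in enumerate(units):
        nc = null_counts[:, ui]
        mean, sd = float(nc.mean()), float(nc.std(ddof=1)) if n > 1 else 0.0
        z = (observed[ui] - mean) / sd if sd > 0 else None
        if randomized_p:
            greater = int(np.sum(nc > observed[ui]))
            ties = int(np.sum(nc == observed[ui]))
            p = (greater + float(rng.uniform()) * (1 + ties)) / (n + 1)
        else:
            p = (1 + int(np.sum(nc >= observed[ui]))) / (n + 1)
        results.append(RegionTestResult(
            dbd=d, observed=observed[ui], n_regions=len(target_regions),
            null_mean=mean, null_sd=sd, z=z, p=float(p)))
    return results


def promoter_test(rna: str, gene_list: Sequence[str], all_genes,
                  genome: Dict[str, str],
                  promoter_window: Tuple[int, int] = (-1500, 500),
                  params: TriplexParams = TriplexParams()):
    """Promoter test: do target-gene promoters form triplexes more often?

    ``gene_list`` names the target genes (must be a subset of ``all_genes``);
    the remaining genes are the non-target group.  The promoter is the
    strand-aware window around the TSS.  Returns a dict with the 2x2 table,
    per-group percentages, and the chi-square p-value.
    """
    from .annotate import RegionScheme, chisq_2x2

    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    by_id = {g.gene_id: g for g in all_genes}
    missing = set(gene_list) - set(by_id)
    if missing:
        raise ValueError(f"genes not in annotation: {sorted(missing)[:5]}")
    scheme = RegionScheme(
        proximal=promoter_window,
        region1=(promoter_window[0], 0),
        region2=(0, promoter_window[1]),
    )
    genome = {c: (s.sequence if isinstance(s, SequenceRecord) else s)
              for c, s in genome.items()}

    def promoters(ids):
        ivs = []
        for gid in ids:
            g = by_id[gid]
            lo, hi = scheme.proximal_window(g)
            hi = min(hi, len(genome[g.chrom]))
            if lo < hi:
                ivs.append(GenomicInterval(g.chrom, lo, hi, g.strand, gid))
        return RegionSet("promoters", ivs)

    target_ids = sorted(set(gene_list))
    nontarget_ids = sorted(set(by_id) - set(target_ids))
    results = {}
    for label, ids in (("target", target_ids), ("non_target", nontarget_ids)):
        proms = promoters(ids)
        hits = find_triplex_hits(rna, proms, genome, params)
        with_dbs = _regions_with_dbs(hits)
        results[label] = {
            "n_genes": len(proms),
            "with_triplex": len(with_dbs),
            "percent": 100.0 * len(with_dbs) / len(proms) if len(proms) else 0.0,
            "genes_with_triplex": sorted(with_dbs),
        }
    a = results["target"]["with_triplex"]
    b = results["target"]["n_genes"] - a
    c = results["non_target"]["with_triplex"]
    d = results["non_target"]["n_genes"] - c
    stat, p = chisq_2x2(a, b, c, d)
    results["table"] = (a, b, c, d)
    results["chisq"] = stat
    results["p"] = p
    return results
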