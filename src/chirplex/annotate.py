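"""TSS-relative annotation of peaks and the random-region permutation null.

The proximal window is a custom, strand-aware definition: -1,500 to +500 bp
around the TSS (so for a minus-strand gene with TSS t the genomic window is
[t-500, t+1500)).  The proximal window splits exactly into region 1
(-1,500/-500, upstream) and region 2 (-500/+500, TSS-centered); cutpeaks are
the intersections of proximal peaks with those sub-windows.

Annotation priority: Proximal > 5'UTR > 3'UTR > Exon > Intron > Downstream >
Distal Intergenic, with nearest-TSS tie-breaking.  Enrichment of the
proximal fraction over random expectation is tested with a Pearson 2x2
chi-square (df=1, no continuity correction) and with empirical p-values over
lists of random length-matched regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, RegionSet, build_tree
from .io import GeneRecord

FEATURE_CATEGORIES = [
    "Proximal Region", "5'UTR", "3'UTR", "Exon", "Intron",
    "Downstream", "Distal Intergenic",
]

OVERLAP_CLASSES = ["includeFeature", "overlapStart", "inside", "overlapEnd"]


@dataclass
class RegionScheme:
    """TSS-relative windows, in transcript orientation (negative = upstream)."""

    proximal: Tuple[int, int] = (-1500, 500)
    downstream_limit: int = 3000
    region1: Tuple[int, int] = (-1500, -500)
    region2: Tuple[int, int] = (-500, 500)

    def __post_init__(self) -> None:
        if (self.region1[0], self.region2[1]) != self.proximal or \
                self.region1[1] != self.region2[0]:
            raise ValueError("region1 and region2 must partition the proximal window")

    def window(self, gene: GeneRecord, rel: Tuple[int, int]) -> Tuple[int, int]:
        """Project a TSS-relative window onto genomic coordinates, half-open."""
        a, b = rel
        t = gene.tss
        if gene.strand == "+":
            lo, hi = t + a, t + b
        else:
            lo, hi = t - b, t - a
        return max(0, lo), max(0, hi)

    def proximal_window(self, gene: GeneRecord) -> Tuple[int, int]:
        return self.window(gene, self.proximal)

    def downstream_window(self, gene: GeneRecord) -> Tuple[int, int]:
        e = gene.gene_end
        if gene.strand == "+":
            return e + 1, e + 1 + self.downstream_limit
        return max(0, e - self.downstream_limit), max(0, e)


def relative_span(peak: GenomicInterval, gene: GeneRecord) -> Tuple[int, int]:
    """Peak span in TSS-relative transcript orientation (continuous projection)."""
    if gene.strand == "+":
        return peak.start - gene.tss, peak.end - gene.tss
    return gene.tss - peak.end, gene.tss - peak.start


@dataclass
class RandomizationParams:
    n_lists: int = 1000
    list_size: int = 5000
    peak_length: int = 775
    seed: int = 0
    proximal_only: bool = False

    def __post_init__(self) -> None:
        if min(self.n_lists, self.list_size, self.peak_length) <= 0:
            raise ValueError("n_lists, list_size and peak_length must be positive")


@dataclass
class CutPeak:
    parent: str
    region_label: str
    interval: GenomicInterval
    gene_id: str


class PeakAnnotator:
    """Assigns each peak one feature category and one gene.

    ``exons``, ``utr5`` and ``utr3`` are optional RegionSets refining the
    gene model; without them only Proximal/Intron/Downstream/Distal are
    reachable (gene bodies lacking sub-structure annotate as Intron).
    """

    def __init__(self, genes: Sequence[GeneRecord], scheme: RegionScheme = RegionScheme(),
                 exons: Optional[RegionSet] = None,
                 utr5: Optional[RegionSet] = None,
                 utr3: Optional[RegionSet] = None) -> None:
        self.genes = list(genes)
        self.scheme = scheme
        self._prox_trees = build_tree(
            GenomicInterval(g.chrom, *scheme.proximal_window(g), g.strand, g.gene_id)
            for g in self.genes
            if scheme.proximal_window(g)[0] < scheme.proximal_window(g)[1]
        )
        self._body_trees = build_tree(g.body for g in self.genes)
        self._down_trees = build_tree(
            GenomicInterval(g.chrom, *scheme.downstream_window(g), g.strand, g.gene_id)
            for g in self.genes
            if scheme.downstream_window(g)[0] < scheme.downstream_window(g)[1]
        )
        self._sub_trees = {
            "5'UTR": build_tree(utr5) if utr5 is not None else {},
            "3'UTR": build_tree(utr3) if utr3 is not None else {},
            "Exon": build_tree(exons) if exons is not None else {},
        }
        self._by_id: Dict[str, GeneRecord] = {g.gene_id: g for g in self.genes}

    def _hits(self, trees: dict, peak: GenomicInterval) -> List[GenomicInterval]:
        tree = trees.get(peak.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(peak.start, peak.end)]

    def _nearest_tss(self, peak: GenomicInterval, gene_ids) -> GeneRecord:
        mid = peak.midpoint
        return min(
            (self._by_id[g] for g in gene_ids),
            key=lambda g: (abs(g.tss - mid), g.gene_id),
        )

    def assign(self, peak: GenomicInterval) -> Tuple[str, Optional[GeneRecord]]:
        """(category, gene); gene is None only for Distal Intergenic."""
        hits = self._hits(self._prox_trees, peak)
        if hits:
            return "Proximal Region", self._nearest_tss(peak, {h.name for h in hits})
        for cat in ("5'UTR", "3'UTR", "Exon"):
            hits = self._hits(self._sub_trees[cat], peak)
            if hits:
                return cat, self._nearest_tss(peak, {h.name for h in hits})
        hits = self._hits(self._body_trees, peak)
        if hits:
            return "Intron", self._nearest_tss(peak, {h.name for h in hits})
        hits = self._hits(self._down_trees, peak)
        if hits:
            return "Downstream", self._nearest_tss(peak, {h.name for h in hits})
        return "Distal Intergenic", None

    def assign_all(self, peaks: Sequence[GenomicInterval]) -> pd.DataFrame:
        rows = []
        for pk in peaks:
            cat, gene = self.assign(pk)
            rows.append({
                "peak": pk.name, "chrom": pk.chrom, "start": pk.start,
                "end": pk.end, "category": cat,
                "gene_id": gene.gene_id if gene else "",
            })
        return pd.DataFrame(
            rows, columns=["peak", "chrom", "start", "end", "category", "gene_id"]
        )


def assign_feature(peak: GenomicInterval, genes: Sequence[GeneRecord],
                   scheme: RegionScheme = RegionScheme(), **kwargs) -> str:
    """One-shot category assignment (see :class:`PeakAnnotator` for batch use)."""
    return PeakAnnotator(genes, scheme, **kwargs).assign(peak)[0]


def feature_distribution(peaks: Sequence[GenomicInterval],
                         genes: Sequence[GeneRecord],
                         scheme: RegionScheme = RegionScheme(),
                         annotator: Optional[PeakAnnotator] = None) -> pd.DataFrame:
    """Counts and percentages per feature category (percentages sum to 100)."""
    ann = annotator or PeakAnnotator(genes, scheme)
    counts = {cat: 0 for cat in FEATURE_CATEGORIES}
    for pk in peaks:
        counts[ann.assign(pk)[0]] += 1
    total = sum(counts.values())
    df = pd.DataFrame({
        "category": FEATURE_CATEGORIES,
        "count": [counts[c] for c in FEATURE_CATEGORIES],
    })
    df["percent"] = 0.0 if total == 0 else 100.0 * df["count"] / total
    return df


def sample_random_regions(params: RandomizationParams, chrom_sizes: Dict[str, int],
                          genes: Optional[Sequence[GeneRecord]] = None,
                          scheme: RegionScheme = RegionScheme()) -> List[RegionSet]:
    """Seeded lists of uniform random fixed-length regions.

    With ``proximal_only`` every region lies fully within some gene's
    proximal window (the 500-random-proximal-peak control).
    """
    rng = np.random.default_rng(params.seed)
    L = params.peak_length
    lists: List[RegionSet] = []
    if params.proximal_only:
        if not genes:
            raise ValueError("proximal_only sampling requires genes")
        windows = []
        for g in genes:
            lo, hi = scheme.proximal_window(g)
            if hi - lo >= L:
                windows.append((g.chrom, lo, hi))
        if not windows:
            raise ValueError("no proximal window can contain peak_length")
        for li in range(params.n_lists):
            idx = rng.integers(0, len(windows), size=params.list_size)
            ivs = []
            for k, wi in enumerate(idx):
                chrom, lo, hi = windows[wi]
                s = int(rng.integers(lo, hi - L + 1))
                ivs.append(GenomicInterval(chrom, s, s + L, name=f"rand{k + 1}"))
            lists.append(RegionSet(f"random_proximal_{li + 1}", ivs))
        return lists

    chroms = [c for c, n in chrom_sizes.items() if n >= L]
    if not chroms:
        raise ValueError("no chromosome can contain peak_length")
    weights = np.array([chrom_sizes[c] - L + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    for li in range(params.n_lists):
        picks = rng.choice(len(chroms), size=params.list_size, p=weights)
        ivs = []
        for k, ci in enumerate(picks):
            chrom = chroms[ci]
            s = int(rng.integers(0, chrom_sizes[chrom] - L + 1))
            ivs.append(GenomicInterval(chrom, s, s + L, name=f"rand{k + 1}"))
        lists.append(RegionSet(f"random_{li + 1}", ivs))
    return lists


def chisq_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-square on [[a,b],[c,d]], df=1, no continuity correction."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: zero row or column margin")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def fold_enrichment(observed_pct: float, expected_pct: float) -> float:
    """Observed/expected ratio of percentages (e.g. 10.23/8.02 ~ 1.3)."""
    if expected_pct <= 0:
        raise ValueError("expected percentage must be positive")
    return observed_pct / expected_pct


def empirical_pvalue(observed_fraction: float,
                     random_list_fractions: Sequence[float],
                     variant: str = "standard",
                     alternative: str = "greater",
                     n_observed: Optional[int] = None,
                     list_size: Optional[int] = None,
                     alpha: float = 0.05) -> float:
    """Permutation p-value of an observed fraction against random-list fractions.

    ``standard``: p = (1 + #{lists as or more extreme}) / (N + 1).

    ``paper``: p = 1/k, where k counts lists whose own 2x2 chi-square against
    the observed counts is significant after Benjamini-Hochberg correction
    across the N lists (p = 1 when k = 0).  Requires ``n_observed`` and
    ``list_size`` to reconstruct counts from fractions.
    """
    fr = np.asarray(random_list_fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("need at least one random list")
    if variant == "standard":
        if alternative == "greater":
            extreme = int(np.sum(fr >= observed_fraction))
        elif alternative == "less":
            extreme = int(np.sum(fr <= observed_fraction))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return (1 + extreme) / (fr.size + 1)
    if variant == "paper":
        if n_observed is None or list_size is None:
            raise ValueError("paper variant needs n_observed and list_size")
        a = int(round(observed_fraction * n_observed))
        pvals = []
        for f in fr:
            c = int(round(f * list_size))
            _, p = chisq_2x2(a, n_observed - a, c, list_size - c)
            pvals.append(p)
        k = int(np.sum(benjamini_hochberg(pvals) <= alpha))
        return 1.0 if k == 0 else 1.0 / k
    raise ValueError(f"unknown variant {variant!r}")


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def tss_profile(peaks: Sequence[GenomicInterval], genes: Sequence[GeneRecord],
                window: int = 1500, binsize: int = 100,
                annotator: Optional[PeakAnnotator] = None) -> pd.Series:
    """Per-bin peak counts around the TSS, oriented 5'->3' of the gene.

    Each peak is projected relative to the TSS of its assigned gene (nearest
    TSS among overlapping windows) and contributes one count to every bin its
    span overlaps.  Bins are labeled by their left (upstream-most) edge.
    """
    if (2 * window) % binsize != 0:
        raise ValueError("binsize must divide 2*window")
    edges = np.arange(-window, window + binsize, binsize)
    counts = np.zeros(len(edges) - 1, dtype=int)
    ann = annotator or PeakAnnotator(genes)
    for pk in peaks:
        _, gene = ann.assign(pk)
        if gene is None:
            continue
        lo, hi = relative_span(pk, gene)
        for i in range(len(edges) - 1):
            if lo < edges[i + 1] and hi > edges[i]:
                counts[i] += 1
    return pd.Series(counts, index=edges[:-1], name="peak_count")


def cut_peaks(assigned: Sequence[Tuple[GenomicInterval, GeneRecord]],
              region: str, scheme: RegionScheme = RegionScheme()) -> List[CutPeak]:
    """Intersect proximal peaks with region1/region2 windows of their genes.

    ``assigned`` pairs each proximal peak with its annotated gene.  Peaks with
    an empty intersection are dropped.
    """
    if region not in ("region1", "region2"):
        raise ValueError("region must be 'region1' or 'region2'")
    rel = scheme.region1 if region == "region1" else scheme.region2
    out: List[CutPeak] = []
    for pk, gene in assigned:
        lo, hi = scheme.window(gene, rel)
        s, e = max(pk.start, lo), min(pk.end, hi)
        if s < e:
            out.append(CutPeak(
                parent=pk.name, region_label=region,
                interval=GenomicInterval(pk.chrom, s, e, gene.strand,
                                         f"{pk.name}_{region}" if pk.name else region),
                gene_id=gene.gene_id,
            ))
    return out


def classify_overlap(assigned: Sequence[Tuple[GenomicInterval, GeneRecord]],
                     scheme: RegionScheme = RegionScheme()) -> pd.DataFrame:
    """Classify how proximal peaks overlap the region-2 window of their gene.

    Classes (in transcript orientation, F = region-2 window): includeFeature
    (peak covers F, starting before it), overlapStart (starts before F, ends
    inside), inside (peak within F), overlapEnd (starts inside F, ends after).
    Percentages are over all proximal peaks; peaks confined to region 1 never
    touch F and make up the remainder (class ``region1Only``).
    """
    f0, f1 = scheme.region2
    counts = {c: 0 for c in OVERLAP_CLASSES + ["region1Only"]}
    for pk, gene in assigned:
        lo, hi = relative_span(pk, gene)
        if hi <= f0 or lo >= f1:
            counts["region1Only"] += 1
        elif lo < f0 and hi >= f1:
            counts["includeFeature"] += 1
        elif lo < f0:
            counts["overlapStart"] += 1
        elif hi <= f1:
            counts["inside"] += 1
        else:
            counts["overlapEnd"] += 1
    total = sum(counts.values())
    df = pd.DataFrame({
        "class": list(counts),
        "count": list(counts.values()),
    })
    df["percent"] = 0.0 if total == 0 else 100.0 * df["count"] / total
    return df
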