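"""DBS-Alu co-occurrence: distances, ranked-bin tables, and the
Jonckheere-Terpstra trend test.

The biological question: when a peak both forms a triplex (carries a DBS)
and contains an Alu repeat, how close are the two, and does the fraction of
genes carrying both decay with the strength of the gene's expression
response?  The trend across ordered fold-change bins is tested with the
nonparametric Jonckheere-Terpstra statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, RegionSet, build_tree

COOCCUR_CLASSES = ["triplex+Alu", "triplex only", "Alu only", "neither"]


@dataclass
class DistanceRecord:
    peak: str
    dbs: GenomicInterval
    nearest_alu: Optional[GenomicInterval]
    gap: Optional[int]  # bp edge-to-edge; 0 when overlapping; None = no Alu

    @property
    def no_alu(self) -> bool:
        return self.nearest_alu is None


def dbs_alu_distance(peaks_with_dbs: Sequence[Tuple[GenomicInterval, GenomicInterval]],
                     alu_track: RegionSet, search_window: int = 1000,
                     near_cutoff: int = 300,
                     include_no_alu_in_denominator: bool = False):
    """Distance from each peak's DBS to its nearest Alu element.

    ``peaks_with_dbs`` pairs each triplex-forming peak with one DBS interval.
    Alu elements overlapping the peak span extended by ``search_window`` bp
    are considered; a peak with none is flagged ``no_alu`` and excluded from
    the summary denominator unless requested otherwise.  Returns
    (records, summary) where summary reports the fraction of records with
    gap < ``near_cutoff``.
    """
    trees = build_tree(alu_track)
    records: List[DistanceRecord] = []
    for peak, dbs in peaks_with_dbs:
        tree = trees.get(peak.chrom)
        best: Optional[GenomicInterval] = None
        best_gap: Optional[int] = None
        if tree is not None:
            lo = max(0, peak.start - search_window)
            hi = peak.end + search_window
            for hit in tree.overlap(lo, hi):
                alu = hit.data
                gap = dbs.distance_to(alu)
                if gap is not None and (best_gap is None or gap < best_gap):
                    best, best_gap = alu, gap
        records.append(DistanceRecord(peak.name, dbs, best, best_gap))
    gaps = [r.gap for r in records if r.gap is not None]
    denom = len(records) if include_no_alu_in_denominator else len(gaps)
    near = sum(1 for g in gaps if g < near_cutoff)
    summary = {
        "n_peaks": len(records),
        "n_with_alu": len(gaps),
        "n_no_alu": len(records) - len(gaps),
        "median_gap": float(np.median(gaps)) if gaps else float("nan"),
        f"fraction_within_{near_cutoff}": near / denom if denom else float("nan"),
    }
    return records, summary


def triplex_alu_table(genes: Sequence[str], dbs_genes: Set[str],
                      alu_genes: Set[str], fold_changes: Dict[str, float],
                      bin_size: int = 20) -> pd.DataFrame:
    """Per-bin percentages of triplex/Alu status over fold-change-ranked genes.

    Genes are ranked by |fold change| descending (ties broken by gene id) and
    cut into consecutive bins of ``bin_size`` (the first bin holds the most
    strongly modulated genes); the final bin may be smaller.  Each gene falls
    in exactly one of four classes; percentages per bin sum to 100.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    missing = [g for g in genes if g not in fold_changes]
    if missing:
        raise ValueError(f"genes without fold change: {missing[:5]}")
    ranked = sorted(genes, key=lambda g: (-abs(fold_changes[g]), g))
    rows = []
    for bi in range(0, len(ranked), bin_size):
        chunk = ranked[bi:bi + bin_size]
        counts = dict.fromkeys(COOCCUR_CLASSES, 0)
        for g in chunk:
            has_dbs, has_alu = g in dbs_genes, g in alu_genes
            if has_dbs and has_alu:
                counts["triplex+Alu"] += 1
            elif has_dbs:
                counts["triplex only"] += 1
            elif has_alu:
                counts["Alu only"] += 1
            else:
                counts["neither"] += 1
        lo, hi = bi + 1, bi + len(chunk)
        row = {"bin": f"top{hi}" if bi == 0 else f"{lo}-{hi}",
               "n_genes": len(chunk)}
        for cls in COOCCUR_CLASSES:
            row[cls] = 100.0 * counts[cls] / len(chunk)
        rows.append(row)
    return pd.DataFrame(rows)


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """JT = sum over group pairs i<j of #{x<y} + 0.5 * #{x==y}."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x, y = groups[i], groups[j]
            less = np.sum(x[:, None] < y[None, :])
            ties = np.sum(x[:, None] == y[None, :])
            jt += float(less) + 0.5 * float(ties)
    return jt


def _jt_moments(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Tie-corrected null mean and variance of the JT statistic."""
    ns = np.array([g.size for g in groups], dtype=float)
    n = float(ns.sum())
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (n ** 2 - np.sum(ns ** 2)) / 4.0
    term1 = (n * (n - 1) * (2 * n + 5)
             - np.sum(ns * (ns - 1) * (2 * ns + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(ns * (ns - 1) * (ns - 2)) * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * n * (n - 1) * (n - 2))) if n > 2 else 0.0
    term3 = (np.sum(ns * (ns - 1)) * np.sum(t * (t - 1))
             / (8.0 * n * (n - 1))) if n > 1 else 0.0
    return mean, term1 + term2 + term3


def jonckheere_terpstra(groups: Sequence[Sequence[float]],
                        alternative: str = "increasing",
                        method: str = "normal",
                        n_permutations: int = 999,
                        seed: int = 0) -> Tuple[float, float]:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    ``alternative='increasing'`` tests for values growing along the group
    order, ``'decreasing'`` for the reverse.  The p-value uses the normal
    approximation with tie-corrected variance, or a seeded permutation of
    pooled values (``method='permutation'``), which is preferable for small
    samples.  Returns (JT statistic, p).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 ordered groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    if alternative not in ("increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    jt = _jt_statistic(arrs)
    if method == "normal":
        mean, var = _jt_moments(arrs)
        if var <= 0:
            return jt, 1.0
        z = (jt - mean) / np.sqrt(var)
        p = stats.norm.sf(z) if alternative == "increasing" else stats.norm.cdf(z)
        return jt, float(p)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(arrs)
        sizes = [a.size for a in arrs]
        extreme = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            jt_p = _jt_statistic(parts)
            if alternative == "increasing":
                extreme += jt_p >= jt
            else:
                extreme += jt_p <= jt
        return jt, (1 + extreme) / (n_permutations + 1)
    raise ValueError(f"unknown method {method!r}")
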