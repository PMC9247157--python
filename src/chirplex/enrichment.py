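"""Region-set enrichment against feature databases.

Follows the LOLA-style contingency construction: the sampling units are the
elements of a *restricted universe* built from the query sets themselves
(their merged union), an element supports a database when it overlaps it by
at least ``min_overlap`` bp, and enrichment of the query within the universe
is summarized by the odds ratio (a*d)/(b*c) of the 2x2 table with a
one-sided (enrichment) exact test.  The triplex-stratified ratio of odds
ratios contrasts triplex-containing and triplex-less peaks against the same
universe and database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import RegionSet, merge_intervals, overlap_flags


@dataclass
class RegionDatabase:
    """A named feature region set, normalized and merged at gap 0."""

    name: str
    regions: RegionSet

    @classmethod
    def from_regions(cls, name: str, regions: RegionSet) -> "RegionDatabase":
        return cls(name, merge_intervals(regions, 0))


@dataclass
class EnrichmentResult:
    query_name: str
    db_name: str
    a: int  # query elements overlapping db
    b: int  # query elements not overlapping db
    c: int  # rest of universe overlapping db
    d: int  # rest of universe not overlapping db
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> Tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def build_restricted_universe(query_sets: Sequence[RegionSet]) -> RegionSet:
    """Merged union of the query sets; every query interval maps to exactly
    one universe element."""
    if not query_sets:
        raise ValueError("need at least one query set")
    pooled = RegionSet("universe", [iv for qs in query_sets for iv in qs])
    return merge_intervals(pooled, 0)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c); inf when b*c = 0 with a*d > 0; nan when both are 0."""
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def region_set_enrichment(query: RegionSet, universe: RegionSet,
                          db: RegionDatabase, min_overlap: int = 1,
                          alternative: str = "greater") -> EnrichmentResult:
    """Enrichment of a query region set against a database within a universe.

    Universe elements overlapping the query form the query stratum; support
    is >= ``min_overlap`` bp overlap with the database.  The p-value is the
    one-sided (greater) exact hypergeometric test by default; ``two-sided``
    switches to Fisher's two-sided test.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    in_query = np.array(overlap_flags(universe.intervals, query, 1))
    in_db = np.array(overlap_flags(universe.intervals, db.regions, min_overlap))
    a = int(np.sum(in_query & in_db))
    b = int(np.sum(in_query & ~in_db))
    c = int(np.sum(~in_query & in_db))
    d = int(np.sum(~in_query & ~in_db))
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(query.name, db.name, a, b, c, d,
                            odds_ratio(a, b, c, d), float(p))


@dataclass
class StratifiedORResult:
    db_name: str
    or_triplex: float
    or_triplexless: float
    ratio: Optional[float]
    triplex_result: EnrichmentResult
    triplexless_result: EnrichmentResult


def stratified_or_ratio(peaks: RegionSet, triplex_flags: Sequence[bool],
                        universe: RegionSet, db: RegionDatabase,
                        min_overlap: int = 1) -> StratifiedORResult:
    """Ratio of odds ratios: triplex-containing vs triplex-less peaks.

    Both strata are tested against the same universe and database; a ratio
    > 1 means the feature is preferentially enriched where the triplex is.
    The ratio is None (flagged undefined) when either stratum's OR is 0,
    infinite or undefined.
    """
    flags = list(triplex_flags)
    if len(flags) != len(peaks):
        raise ValueError("one flag per peak required")
    tri = RegionSet(f"{peaks.name}_triplex",
                    [iv for iv, f in zip(peaks, flags) if f])
    notri = RegionSet(f"{peaks.name}_triplexless",
                      [iv for iv, f in zip(peaks, flags) if not f])
    if len(tri) == 0 or len(notri) == 0:
        raise ValueError("both strata must be non-empty")
    r_tri = region_set_enrichment(tri, universe, db, min_overlap)
    r_no = region_set_enrichment(notri, universe, db, min_overlap)
    ot, on = r_tri.odds_ratio, r_no.odds_ratio
    # degenerate tables (a zero cell) drive an OR to 0 or inf; the ratio is
    # still directional when the two ORs disagree coherently, undefined when
    # both collapse the same way
    if np.isnan(ot) or np.isnan(on):
        ratio: Optional[float] = None
    elif (np.isinf(ot) and np.isinf(on)) or (ot == 0 and on == 0):
        ratio = None
    elif np.isinf(ot) or on == 0:
        ratio = float("inf")
    elif np.isinf(on) or ot == 0:
        ratio = 0.0
    else:
        ratio = ot / on
    return StratifiedORResult(db.name, ot, on, ratio, r_tri, r_no)
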