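"""Genomic interval data model and interval algebra.

Everything downstream (peaks, promoter windows, cutpeaks, triplex target
sites, repeat annotations) is expressed as :class:`GenomicInterval` objects
collected into :class:`RegionSet` containers.  Coordinates are uniformly
0-based half-open, the BED convention; any 1-based report output elsewhere in
the package is explicitly labeled as such.

Chromosome names are taken verbatim.  There is deliberately no ``chr``
normalization: a naming mismatch between two inputs raises instead of
producing a silent empty join.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A located span on a chromosome, 0-based half-open.

    ``strand`` defaults to ``.`` (unstranded); ``score`` may be absent.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"negative start {self.start} for interval on {self.chrom}"
            )
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Edge-to-edge gap in bp; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class NarrowPeakRecord:
    """An ENCODE narrowPeak call: interval plus summit offset and signal.

    ``summit_offset`` is measured from ``interval.start``; -1 means unknown,
    in which case :attr:`center` falls back to the interval midpoint.
    """

    interval: GenomicInterval
    summit_offset: int = -1
    signal: float = 0.0
    neglog10_p: float = -1.0
    neglog10_q: float = -1.0

    def __post_init__(self) -> None:
        if not (-1 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )

    @property
    def center(self) -> int:
        if self.summit_offset >= 0:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass
class RegionSet:
    """A named collection of intervals, optionally carrying narrowPeak records.

    ``records``, when present, is aligned index-for-index with ``intervals``.
    """

    name: str = ""
    intervals: list = field(default_factory=list)
    records: Optional[list] = None
    is_sorted: bool = False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def chroms(self) -> set:
        return {iv.chrom for iv in self.intervals}

    def normalized(self) -> "RegionSet":
        """Sorted copy (by chrom, start, end); records follow their intervals."""
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        recs = [self.records[i] for i in order] if self.records is not None else None
        return RegionSet(
            name=self.name,
            intervals=[self.intervals[i] for i in order],
            records=recs,
            is_sorted=True,
        )

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def build_tree(regions: Iterable[GenomicInterval]) -> dict:
    """Per-chromosome IntervalTree of the given intervals (data = interval)."""
    trees: dict = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def merge_intervals(regions: RegionSet, max_gap: int = 0) -> RegionSet:
    """Merge intervals separated by at most ``max_gap`` bp.

    With ``max_gap=0`` this is the plain union: output intervals are pairwise
    non-overlapping and cover exactly the same bases.  Book-keeping fields
    (strand, score) are dropped; each merged interval is named after its first
    member when that member carried a name.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    srt = regions.normalized()
    merged: list = []
    cur = None
    for iv in srt.intervals:
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end + max_gap:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name)
    if cur is not None:
        merged.append(cur)
    return RegionSet(name=regions.name, intervals=merged, is_sorted=True)


def overlap_count(query: RegionSet, subject: RegionSet, min_bp: int = 1) -> int:
    """Number of query intervals overlapping >= ``min_bp`` bp of some subject interval."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = build_tree(subject)
    n = 0
    for q in query:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            if min(q.end, hit.end) - max(q.start, hit.begin) >= min_bp:
                n += 1
                break
    return n


def overlap_flags(query: Sequence[GenomicInterval], subject: Iterable[GenomicInterval],
                  min_bp: int = 1) -> list:
    """Boolean per query interval: overlaps >= min_bp with some subject interval."""
    trees = build_tree(subject)
    flags = []
    for q in query:
        tree = trees.get(q.chrom)
        found = False
        if tree is not None:
            for hit in tree.overlap(q.start, q.end):
                if min(q.end, hit.end) - max(q.start, hit.begin) >= min_bp:
                    found = True
                    break
        flags.append(found)
    return flags
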