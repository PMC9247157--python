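"""Consensus peak derivation across replicate ChIRP/ChIP experiments.

Each replicate peak is anchored at its center (MACS2 summit when available,
interval midpoint otherwise) and extended by ``extend_size`` bp on both
sides.  Overlapping extended regions, pooled across replicates, form
connected components; a component supported by at least ``min_support``
distinct replicates becomes a consensus peak.  When every member's narrow
(original) region lies inside the component's extended span, the consensus
interval shrinks to the minimal interval covering the narrow regions.

Chained overlaps (A overlaps B, B overlaps C, A does not overlap C) are
resolved as a single consensus region: the component is the transitive
closure of pairwise overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

from .intervals import GenomicInterval, NarrowPeakRecord, RegionSet


@dataclass
class ConsensusParams:
    min_support: int = 2
    n_replicates: int = 3
    extend_size: int = 500
    shrink_to_fit: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_support <= self.n_replicates:
            raise ValueError("require 1 <= min_support <= n_replicates")
        if self.extend_size <= 0:
            raise ValueError("extend_size must be positive")


@dataclass
class ConsensusPeak:
    """A replicate-supported consensus region with member provenance."""

    interval: GenomicInterval
    support: int
    members: List = field(default_factory=list)  # (replicate id, NarrowPeakRecord)


def _as_records(region_set: RegionSet) -> List[NarrowPeakRecord]:
    if region_set.records is not None:
        return list(region_set.records)
    return [NarrowPeakRecord(iv) for iv in region_set]


def find_consensus_peaks(replicate_peaks: Sequence[RegionSet],
                         params: ConsensusParams = ConsensusParams()
                         ) -> List[ConsensusPeak]:
    """Derive consensus peaks from >= ``params.n_replicates`` replicate sets.

    Support counts distinct replicates, not peaks: two peaks contributed by
    the same replicate to one component count once.  Output is sorted by
    (chrom, start) and pairwise non-overlapping.
    """
    if len(replicate_peaks) < params.n_replicates:
        raise ValueError(
            f"need >= {params.n_replicates} replicate sets, got {len(replicate_peaks)}"
        )
    entries = []  # (chrom, ext_start, ext_end, rep_id, record)
    for rep_id, rset in enumerate(replicate_peaks):
        for rec in _as_records(rset):
            c = rec.center
            entries.append((
                rec.interval.chrom,
                max(0, c - params.extend_size),
                c + params.extend_size,
                rep_id,
                rec,
            ))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    peaks: List[ConsensusPeak] = []
    component: list = []
    comp_chrom, comp_end = None, None

    def flush() -> None:
        if not component:
            return
        reps = {rep for _, _, _, rep, _ in component}
        if len(reps) >= params.min_support:
            ext_start = min(e[1] for e in component)
            ext_end = max(e[2] for e in component)
            narrow_start = min(e[4].interval.start for e in component)
            narrow_end = max(e[4].interval.end for e in component)
            if (params.shrink_to_fit and narrow_start >= ext_start
                    and narrow_end <= ext_end):
                start, end = narrow_start, narrow_end
            else:
                start, end = ext_start, ext_end
            members = sorted(
                ((rep, rec) for _, _, _, rep, rec in component),
                key=lambda m: (m[0], m[1].interval.start, m[1].interval.end),
            )
            peaks.append(ConsensusPeak(
                GenomicInterval(comp_chrom, start, end,
                                name=f"consensus_{len(peaks) + 1}"),
                support=len(reps),
                members=members,
            ))

    for entry in entries:
        chrom, ext_start, ext_end = entry[0], entry[1], entry[2]
        if component and chrom == comp_chrom and ext_start < comp_end:
            component.append(entry)
            comp_end = max(comp_end, ext_end)
        else:
            flush()
            component = [entry]
            comp_chrom, comp_end = chrom, ext_end
    flush()

    for i, pk in enumerate(peaks, start=1):
        pk.interval.name = f"consensus_{i}"
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def consensus_region_set(peaks: Sequence[ConsensusPeak],
                         name: str = "consensus") -> RegionSet:
    return RegionSet(name=name, intervals=[p.interval for p in peaks],
                     is_sorted=True)
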