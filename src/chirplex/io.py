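"""Readers and writers for the plain-text formats the pipeline touches.

Supported dialects:

* BED6 and ENCODE narrowPeak (10 columns), exactly per the UCSC/ENCODE
  definitions, 0-based half-open;
* FASTA for genome / lncRNA sequences (via Biopython);
* gene tables as BED6 (span + strand; TSS and termination derived);
* per-base single-strandedness profiles as 2-column TSV (1-based position,
  probability in [0, 1]).

Malformed lines raise with the offending line number.  Lines starting with
``#`` or ``track``/``browser`` are skipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, NarrowPeakRecord, RegionSet

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")


@dataclass
class GeneRecord:
    """A gene anchored by its TSS and termination position.

    ``tss`` and ``gene_end`` are 0-based positions of the first and last
    transcribed base; for a ``-`` strand gene ``tss > gene_end``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0 or self.gene_end < 0:
            raise ValueError(f"gene {self.gene_id}: negative coordinate")

    @property
    def body(self) -> GenomicInterval:
        lo, hi = sorted((self.tss, self.gene_end))
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand, self.gene_id)


@dataclass
class SequenceRecord:
    """A named nucleotide sequence; RNA records may contain U, DNA may not."""

    id: str
    sequence: str
    moltype: str = "DNA"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        alpha = RNA_ALPHABET if self.moltype == "RNA" else DNA_ALPHABET
        bad = set(self.sequence) - alpha
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_interval(path, lineno, fields, n_required):
    if len(fields) < n_required:
        raise ValueError(
            f"{path}:{lineno}: expected >= {n_required} columns, got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start >= end:
        raise ValueError(
            f"{path}:{lineno}: start {start} >= end {end} (inverted/empty interval)"
        )
    name = fields[3] if len(fields) > 3 else ""
    score: Optional[float] = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] else "."
    try:
        return GenomicInterval(chrom, start, end, strand, name, score)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_region_file(path: str, dialect: str = "bed6") -> RegionSet:
    """Read a BED6 or narrowPeak file into a RegionSet.

    For ``narrowPeak`` the returned set also carries aligned
    :class:`NarrowPeakRecord` objects in ``.records`` (summit offset from
    column 10; -1 means unknown).
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    intervals, records = [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if dialect == "bed6":
            intervals.append(_parse_interval(path, lineno, fields, 3))
        else:
            iv = _parse_interval(path, lineno, fields, 10)
            try:
                signal = float(fields[6])
                neglog_p = float(fields[7])
                neglog_q = float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed narrowPeak columns 7-10"
                ) from exc
            try:
                rec = NarrowPeakRecord(iv, summit, signal, neglog_p, neglog_q)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
            records.append(rec)
    name = os.path.splitext(os.path.basename(path))[0]
    return RegionSet(
        name=name,
        intervals=intervals,
        records=records if dialect == "narrowPeak" else None,
    )


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_region_file(regions: RegionSet, path: str, dialect: str = "bed6",
                      header: Optional[str] = None) -> None:
    """Write a RegionSet as BED6 or narrowPeak; inverse of :func:`read_region_file`."""
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for i, iv in enumerate(regions):
            base = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".",
                    _fmt_score(iv.score), iv.strand]
            if dialect == "bed6":
                fh.write("\t".join(base) + "\n")
            else:
                rec = (regions.records[i] if regions.records is not None
                       else NarrowPeakRecord(iv))
                fh.write("\t".join(base + [
                    repr(float(rec.signal)),
                    repr(float(rec.neglog10_p)),
                    repr(float(rec.neglog10_q)),
                    str(rec.summit_offset),
                ]) + "\n")


def read_fasta(path: str, moltype: str = "DNA") -> dict:
    """FASTA -> {id: SequenceRecord}; order preserved (py>=3.7 dicts)."""
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = SequenceRecord(rec.id, str(rec.seq), moltype)
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(records, path: str, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line" if width == 0 else "fasta")


def read_genes(path: str) -> list:
    """Gene BED6 -> GeneRecords.  TSS is the 5' end of the span per strand."""
    genes = []
    for lineno, line in _data_lines(path):
        iv = _parse_interval(path, lineno, line.split("\t"), 6)
        if iv.strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: gene strand must be + or -")
        if iv.strand == "+":
            tss, gene_end = iv.start, iv.end - 1
        else:
            tss, gene_end = iv.end - 1, iv.start
        genes.append(GeneRecord(iv.name or f"gene{lineno}", iv.chrom, iv.strand,
                                tss, gene_end))
    return genes


def write_genes(genes, path: str, header: Optional[str] = None) -> None:
    ivs = []
    for g in genes:
        lo, hi = sorted((g.tss, g.gene_end))
        ivs.append(GenomicInterval(g.chrom, lo, hi + 1, g.strand, g.gene_id, 0))
    write_region_file(RegionSet("genes", ivs), path, "bed6", header=header)


def read_accessibility_profile(path: str, rna_length: Optional[int] = None) -> np.ndarray:
    """2-column TSV (1-based position, P(single-stranded)) -> float vector."""
    positions, probs = [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        try:
            pos, p = int(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed profile line") from exc
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{path}:{lineno}: probability {p} outside [0,1]")
        positions.append(pos)
        probs.append(p)
    if positions != list(range(1, len(positions) + 1)):
        raise ValueError(f"{path}: positions must run 1..N without gaps")
    if rna_length is not None and len(probs) != rna_length:
        raise ValueError(
            f"{path}: profile length {len(probs)} != RNA length {rna_length}"
        )
    return np.asarray(probs, dtype=float)


def write_accessibility_profile(profile, path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(profile, start=1):
            fh.write(f"{i}\t{float(p):.6f}\n")
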