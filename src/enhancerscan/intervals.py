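"""Genomic interval data model and plain-text genomics I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package.  Overlap requires at least one shared base pair, the default
behaviour of ``bedtools intersect``.  Strand is carried through I/O but
ignored by every overlap and feature computation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "FeatureTrack",
    "VistaRecord",
    "GenomeAssembly",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_vista_table",
    "write_vista_table",
    "overlaps_any",
]


class BedParseError(ValueError):
    """Raised for malformed interval lines; message carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp shared, half-open semantics; strand ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class FeatureTrack:
    """A named, sorted collection of intervals with an indexed overlap query.

    Intervals are kept sorted by ``(chrom, start, end)``; queries go through
    a per-chromosome interval tree, so lookup cost is logarithmic in the
    track size rather than linear.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval] = ()):
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All intervals sharing >=1 bp with ``query``, in sorted order."""
        tree = self._index().get(query.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def overlaps_any(self, query: GenomicInterval) -> bool:
        tree = self._index().get(query.chrom)
        return bool(tree is not None and tree.overlaps(query.start, query.end))

    def total_bp(self) -> int:
        """Total bases covered (union, no double counting)."""
        total = 0
        last_chrom = None
        cur_start = cur_end = 0
        for iv in self.intervals:
            if iv.chrom != last_chrom or iv.start > cur_end:
                if last_chrom is not None:
                    total += cur_end - cur_start
                last_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        if last_chrom is not None:
            total += cur_end - cur_start
        return total


def overlaps_any(query: GenomicInterval, track: FeatureTrack) -> bool:
    """True iff ``query`` shares >=1 bp with some interval of ``track``."""
    return track.overlaps_any(query)


@dataclass(frozen=True)
class VistaRecord:
    """One experimentally tested region: active iff it drove expression in
    at least one tissue at the assayed stage."""

    id: str
    interval: GenomicInterval
    tissues: frozenset[str]

    @property
    def active(self) -> bool:
        return bool(self.tissues)


@dataclass
class GenomeAssembly:
    """In-memory genome: sequences, chromosome sizes, and assembly gaps."""

    sequences: dict[str, str] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)
    gaps: FeatureTrack = field(default_factory=lambda: FeatureTrack("gaps"))

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if chrom in self.sizes and self.sizes[chrom] != len(seq):
                raise ValueError(
                    f"size mismatch for {chrom}: sizes says {self.sizes[chrom]}, "
                    f"sequence has {len(seq)}"
                )
        for chrom, seq in self.sequences.items():
            self.sizes.setdefault(chrom, len(seq))

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; errors if out of chromosome bounds."""
        seq = self.sequences.get(interval.chrom)
        if seq is None:
            raise KeyError(f"chromosome {interval.chrom} not in assembly")
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


# ---------------------------------------------------------------------------
# BED / narrowPeak / broadPeak

_BED_DIALECTS = ("bed", "narrowPeak", "broadPeak")


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
    score: float | None = None
    if len(fields) > 4 and fields[4] not in ("", "."):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else None
    try:
        return GenomicInterval(chrom, start, end, name, score, strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path: str | Path, dialect: str = "bed", name: str | None = None) -> FeatureTrack:
    """Read a BED-family file into a sorted :class:`FeatureTrack`.

    narrowPeak/broadPeak lines carry extra statistics columns; only the
    first six (chrom/start/end/name/score/strand) are kept.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_BED_DIALECTS}")
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_bed_line(line, lineno))
    return FeatureTrack(name or path.stem, intervals)


def write_bed(track: FeatureTrack, path: str | Path) -> None:
    """Write a track as BED; emits exactly the columns that are populated."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(_format_score(iv.score) if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


# ---------------------------------------------------------------------------
# FASTA and chrom.sizes


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read FASTA into a :class:`GenomeAssembly` (names up to first whitespace)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r}")
        sequences[record.id] = str(record.seq)
    return GenomeAssembly(sequences=sequences)


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected chrom<TAB>size")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# VISTA-style truth table


def read_vista_table(path: str | Path) -> list[VistaRecord]:
    """Read a tab-separated truth table: id, chrom, start, end, tissues.

    The tissue column is semicolon-separated; an empty field marks a region
    that was tested and showed no activity.  Coordinates are taken as
    already 0-based half-open.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"line {lineno}: expected id, chrom, start, end[, tissues]"
                )
            rid, chrom = fields[0], fields[1]
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            tissue_field = fields[4] if len(fields) > 4 else ""
            tissues = frozenset(t.strip() for t in tissue_field.split(";") if t.strip())
            try:
                interval = GenomicInterval(chrom, start, end, name=rid)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            records.append(VistaRecord(rid, interval, tissues))
    return records


def write_vista_table(records: Sequence[VistaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tissues = ";".join(sorted(rec.tissues))
            iv = rec.interval
            fh.write(f"{rec.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{tissues}\n")
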