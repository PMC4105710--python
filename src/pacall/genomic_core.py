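"""Coordinate conventions, interval arithmetic and sequence utilities.

Every internal coordinate in this package is 0-based, half-open (BED
convention): an interval ``[start, end)`` covers ``end - start`` bases.
1-based formats (GFF3, SAM POS) are converted at the I/O boundary.

For stranded data the cleavage coordinate of a read is the position of the
last *transcribed* base before the poly(A) tail: on the plus strand this is
the rightmost aligned genomic base, on the minus strand the leftmost.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "GenomicInterval",
    "CleavageEvent",
    "BedRecord",
    "reverse_complement",
    "merge_intervals",
    "read_bed6",
    "write_bed6",
    "fetch",
    "contig_length",
    "atomic_write",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTNacgtn")

STRANDS = ("+", "-", ".")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Raises ``ValueError`` on characters outside ``{A, C, G, T, N}``
    (case-insensitive).
    """
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class CleavageEvent:
    """One accepted read reduced to its cleavage position.

    ``coord`` is the last transcribed base before the poly(A) tail; the tail
    starts directly after this position in transcript orientation.
    """

    chrom: str
    strand: str
    coord: int
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"cleavage events are stranded, got {self.strand!r}")
        if self.coord < 0:
            raise ValueError("coord must be >= 0")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping *and* book-ended intervals on one chrom/strand.

    Intervals that touch end-to-start are merged (BEDtools ``merge`` default).
    The union of covered bases is preserved. Mixed chromosomes or strands are
    rejected: callers merge per (chrom, strand) group.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("merge_intervals requires a single chrom and strand")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_start, cur_end = ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.start <= cur_end:  # overlap or adjacency
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(ordered[0].chrom, cur_start, cur_end, ordered[0].strand))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(ordered[0].chrom, cur_start, cur_end, ordered[0].strand))
    return merged


@dataclass(frozen=True)
class BedRecord:
    """One BED6 line: chrom, start, end, name, score, strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "."

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def read_bed6(path: Union[str, os.PathLike]) -> Iterator[BedRecord]:
    """Iterate BED6 records, skipping comment/track/empty lines."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            yield BedRecord(chrom, start, end, name, score, strand)


def write_bed6(records: Iterable[BedRecord], path: Union[str, os.PathLike]) -> None:
    with atomic_write(path) as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.score}\t{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# Sequence access
#
# Genome sequences are accepted either as an in-memory mapping
# {chrom: str | bytes | bytearray} (what the synthetic generator produces) or
# as a pyfaidx.Fasta for random access into an indexed FASTA on disk.
# ---------------------------------------------------------------------------

GenomeLike = Union[Mapping[str, object], "pyfaidx.Fasta"]  # noqa: F821


def _as_str(chunk: object) -> str:
    if isinstance(chunk, str):
        return chunk
    if isinstance(chunk, (bytes, bytearray)):
        return chunk.decode("ascii")
    return str(chunk)


def fetch(genome: GenomeLike, chrom: str, start: int, end: int) -> str:
    """Return genome[chrom][start:end] (0-based half-open), uppercase."""
    start = max(0, start)
    if end <= start:
        return ""
    seq = genome[chrom][start:end]
    return _as_str(seq).upper()


def contig_length(genome: GenomeLike, chrom: str) -> int:
    return len(genome[chrom])


def contig_names(genome: GenomeLike) -> list[str]:
    return list(genome.keys())


@contextmanager
def atomic_write(path: Union[str, os.PathLike]):
    """Write to a temp file in the target directory, then rename into place.

    Interrupted runs never leave a truncated output file.
    """
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp.", suffix=".part")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
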