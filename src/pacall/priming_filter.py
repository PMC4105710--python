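"""Genomic A-stretch discovery and internal-priming artifact removal.

Oligo(dT) priming can anneal to A-rich stretches *inside* a transcript
instead of the true poly(A) tail (even eight adenines within 10 bases
suffice at room temperature), producing truncated cDNAs whose 3' ends mimic
cleavage sites. Such events are removed in two steps:

1. ``find_a_stretches`` scans the reference for every 10-mer window with at
   most two non-A bases (strand-oriented: A-runs on the plus strand, T-runs
   on the minus strand, since priming chemistry is strand-specific) and
   merges overlapping/adjacent windows into stretches.
2. ``filter_internal_priming`` discards a cleavage event when a same-strand
   stretch contains its coordinate or begins within a small window
   immediately downstream of it in transcript orientation.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genomic_core import (
    BedRecord,
    CleavageEvent,
    GenomeLike,
    GenomicInterval,
    contig_names,
    fetch,
    contig_length,
)

__all__ = ["AStretch", "find_a_stretches", "filter_internal_priming",
           "stretches_to_bed", "stretches_from_bed"]


@dataclass(frozen=True, order=True)
class AStretch:
    """A merged homopolymeric adenine stretch (strand-oriented)."""

    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


def _seed_windows(is_match: np.ndarray, k: int, max_mismatch: int) -> list[tuple[int, int]]:
    """Merged [start, end) spans of k-windows with <= max_mismatch non-matches."""
    n = is_match.size
    if n < k:
        return []
    counts = np.convolve(is_match.astype(np.int32), np.ones(k, dtype=np.int32), "valid")
    seeds = np.flatnonzero(counts >= k - max_mismatch)
    if seeds.size == 0:
        return []
    spans: list[tuple[int, int]] = []
    run_start = prev = int(seeds[0])
    for s in seeds[1:]:
        s = int(s)
        # windows [prev, prev+k) and [s, s+k) merge when s <= prev + k
        if s <= prev + k:
            prev = s
        else:
            spans.append((run_start, prev + k))
            run_start = prev = s
    spans.append((run_start, prev + k))
    return spans


def find_a_stretches(
    genome: GenomeLike, k: int = 10, max_mismatch: int = 2
) -> list[AStretch]:
    """Locate merged adenine stretches on both strands of a genome.

    Equivalent to aligning a ``k``-mer of A against the reference allowing
    ``max_mismatch`` errors at every position, then merging overlapping hits;
    implemented as a direct sliding-window count. Output is sorted by
    (chrom, start, strand) and deterministic.
    """
    stretches: list[AStretch] = []
    for chrom in contig_names(genome):
        seq = fetch(genome, chrom, 0, contig_length(genome, chrom))
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for strand, base in (("+", b"A"), ("-", b"T")):
            for start, end in _seed_windows(arr == base[0], k, max_mismatch):
                stretches.append(AStretch(GenomicInterval(chrom, start, end, strand)))
    stretches.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return stretches


def filter_internal_priming(
    events: Iterable[CleavageEvent],
    stretches: Sequence[AStretch],
    adjacency: int = 10,
) -> tuple[list[CleavageEvent], list[CleavageEvent]]:
    """Partition events into (kept, discarded) by A-stretch adjacency.

    An event is discarded iff a stretch on the *same strand* either contains
    its cleavage coordinate or starts within ``adjacency`` bases immediately
    downstream of it in transcript orientation:

    * plus strand:  ``stretch.start in (coord, coord + adjacency]``
    * minus strand: ``stretch.end   in (coord - adjacency, coord]``

    (On the minus strand "downstream" runs toward lower coordinates, and the
    stretch's transcript-orientation 5' edge is its half-open ``end``.)
    """
    index: dict[tuple[str, str], tuple[list[int], list[tuple[int, int]]]] = {}
    for key, group in _group_stretches(stretches).items():
        group.sort()
        index[key] = ([s for s, _ in group], group)

    kept: list[CleavageEvent] = []
    discarded: list[CleavageEvent] = []
    for ev in events:
        entry = index.get((ev.chrom, ev.strand))
        if entry is None:
            kept.append(ev)
            continue
        starts, group = entry
        # candidate stretches with start <= coord + adjacency and end > coord - adjacency
        hi = bisect_right(starts, ev.coord + adjacency)
        hit = False
        for start, end in group[max(0, hi - 64) : hi]:  # stretches are short; small back-scan
            if end <= ev.coord - adjacency:
                continue
            if start <= ev.coord < end:  # containment
                hit = True
                break
            if ev.strand == "+" and ev.coord < start <= ev.coord + adjacency:
                hit = True
                break
            if ev.strand == "-" and ev.coord - adjacency < end <= ev.coord:
                hit = True
                break
        (discarded if hit else kept).append(ev)
    return kept, discarded


def _group_stretches(
    stretches: Sequence[AStretch],
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in stretches:
        grouped.setdefault((s.chrom, s.strand), []).append((s.start, s.end))
    return grouped


def stretches_to_bed(stretches: Sequence[AStretch]) -> list[BedRecord]:
    return [
        BedRecord(s.chrom, s.start, s.end, f"Astretch{i + 1:05d}", "0", s.strand)
        for i, s in enumerate(stretches)
    ]


def stretches_from_bed(records: Iterable[BedRecord]) -> list[AStretch]:
    return [AStretch(rec.interval()) for rec in records]
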