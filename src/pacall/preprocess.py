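"""Quality trimming and de-novo poly(A)-tail detection/clipping of raw reads.

3'-end libraries capture cDNA fragments ending in the poly(A) tail. The raw
read therefore looks like ``genomic insert + poly(A) tail [+ low-quality
junk]``. The stages here are, in order:

1. ``trim_low_quality`` — remove the maximal terminal run of bases with
   Phred quality below a threshold (default 16, the Illumina Q2 read-segment
   convention) from each end of the read. Interior quality dips are kept.
2. ``detect_polya`` — slide a 5-base window from the 3' end toward the 5'
   end; a window passes while it contains at least 4 adenines (one base is a
   margin for sequencing errors). A read is poly(A)-positive when the window
   has successfully moved at least 7 steps before the first failure, which
   corresponds to a minimum tail of roughly 10-12 nt.
3. ``clip_polya`` — cut the tail off a positive read so only the mappable
   genomic insert remains; reads whose insert is too short for confident
   mapping are rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomic_core import atomic_write

__all__ = [
    "Read",
    "PolyACall",
    "trim_low_quality",
    "detect_polya",
    "clip_polya",
    "read_fastq",
    "write_fastq",
]

#: rejection reasons carried on PolyACall
NO_TAIL = "no_tail"
ALL_TAIL_TOO_SHORT = "all_tail_too_short"


@dataclass(frozen=True)
class Read:
    """A sequencing read (5'->3') with Phred+33 qualities."""

    read_id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: seq length {len(self.seq)} != qual length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PolyACall:
    """Outcome of the sliding-window tail scan on one read.

    ``steps_moved`` counts completed window movements away from the 3' end;
    ``tail_start`` is the index of the first tail base (defined only for
    positive calls).
    """

    is_positive: bool
    steps_moved: int
    tail_start: Optional[int] = None
    reject_reason: Optional[str] = None


def trim_low_quality(read: Read, min_q: int = 16) -> Read:
    """Clip the maximal terminal run of bases with quality < ``min_q``.

    Applied to both ends; interior low-quality bases are retained. May return
    an empty read (the caller discards reads too short to map). Idempotent.
    """
    lo, hi = 0, len(read)
    while lo < hi and read.quals[lo] < min_q:
        lo += 1
    while hi > lo and read.quals[hi - 1] < min_q:
        hi -= 1
    if lo == 0 and hi == len(read):
        return read
    return Read(read.read_id, read.seq[lo:hi], read.quals[lo:hi])


def detect_polya(
    seq: str, window: int = 5, min_a: int = 4, min_steps: int = 7
) -> PolyACall:
    """Sliding-window poly(A)-tail detection on the 3' end of ``seq``.

    The window initially covers the 3'-terminal ``window`` bases (step 0) and
    shifts one base toward the 5' end per step. A window passes when it holds
    at least ``min_a`` adenines. Scanning stops at the first failing window or
    when the window reaches the 5' end; the read is positive when at least
    ``min_steps`` movements completed before the stop.

    For positive calls the tail boundary is the start of the last passing
    window, advanced 3'-ward past any leading non-A bases so the one-mismatch
    margin never leaves genomic bases inside the clipped tail.
    """
    n = len(seq)
    if n < window:
        return PolyACall(False, 0, reject_reason=NO_TAIL)
    seq = seq.upper()
    start = n - window
    steps = 0
    last_pass: Optional[int] = None
    while True:
        if seq[start : start + window].count("A") >= min_a:
            last_pass = start
            if start == 0:
                break
            start -= 1
            steps += 1
        else:
            break
    if last_pass is None or steps < min_steps:
        return PolyACall(False, steps, reject_reason=NO_TAIL)
    tail_start = last_pass
    while seq[tail_start] != "A":  # min_a >= 1 guarantees an A in the window
        tail_start += 1
    return PolyACall(True, steps, tail_start=tail_start)


def clip_polya(
    read: Read, call: Optional[PolyACall] = None, min_remaining: int = 20
) -> Optional[Read]:
    """Truncate a poly(A)-positive read at its tail start.

    Qualities are truncated in lockstep. Returns ``None`` (and records
    ``all_tail_too_short`` on the call) when fewer than ``min_remaining``
    mappable bases remain. Calling this on a negative read is a contract
    violation.
    """
    if call is None:
        call = detect_polya(read.seq)
    if not call.is_positive:
        raise ValueError("clip_polya requires a poly(A)-positive call")
    assert call.tail_start is not None
    if call.tail_start < min_remaining:
        call.reject_reason = ALL_TAIL_TOO_SHORT
        return None
    return Read(read.read_id, read.seq[: call.tail_start], read.quals[: call.tail_start])


# -- FASTQ I/O ---------------------------------------------------------------


def read_fastq(path: Union[str, os.PathLike]) -> Iterator[Read]:
    """Iterate Sanger/Phred+33 FASTQ records as Read objects."""
    for rec in SeqIO.parse(os.fspath(path), "fastq"):
        yield Read(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[Read], path: Union[str, os.PathLike]) -> int:
    """Write reads as Sanger FASTQ; returns the number written."""
    n = 0
    with atomic_write(path) as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.seq), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.quals)
            fh.write(rec.format("fastq"))
            n += 1
    return n
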