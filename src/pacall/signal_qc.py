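"""Poly(A)-signal QC and PA-site set comparison.

True cleavage sites are directed by a signal motif (canonically AAUAAA, or
the degenerate AWUAAA) located roughly 20-30 nt upstream; scanning the 50 nt
upstream of each called site for the signal is a standard sanity check on a
PA-site set. This module extracts upstream windows in transcript
orientation, scans them for IUPAC motifs, and intersects two PA-site sets at
a positional tolerance (one-to-one, nearest first).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .clustering import PACluster
from .genomic_core import (
    GenomeLike,
    atomic_write,
    contig_length,
    fetch,
    reverse_complement,
)

__all__ = [
    "IUPAC",
    "MotifHit",
    "extract_upstream",
    "scan_motif",
    "motif_frequency",
    "intersect_pa_sets",
    "write_upstream_fasta",
]

#: IUPAC nucleotide degeneracy (DNA alphabet; U normalizes to T)
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a cluster's upstream window."""

    cluster: str
    motif: str
    offset: int  # 0-based offset of the motif start within the window


class UpstreamWindow(NamedTuple):
    seq: str
    truncated: bool


def extract_upstream(
    cluster: PACluster, genome: GenomeLike, n: int = 50
) -> UpstreamWindow:
    """The ``n`` bases upstream of the cluster median, 5'->3' in transcript
    orientation, excluding the cleavage base itself.

    Plus strand: ``genome[median - n, median)``; minus strand: the reverse
    complement of ``genome[median + 1, median + 1 + n)``. Windows truncated
    at contig boundaries are flagged.
    """
    median = cluster.median_coord
    if cluster.strand == "+":
        lo = max(0, median - n)
        seq = fetch(genome, cluster.chrom, lo, median)
    else:
        clen = contig_length(genome, cluster.chrom)
        hi = min(clen, median + 1 + n)
        seq = reverse_complement(fetch(genome, cluster.chrom, median + 1, hi))
    return UpstreamWindow(seq, truncated=len(seq) < n)


def _motif_pattern(motif: str) -> re.Pattern[str]:
    motif = motif.upper().replace("U", "T")
    try:
        body = "".join(f"[{IUPAC[c]}]" for c in motif)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in motif {motif!r}: {exc}") from exc
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def scan_motif(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) offsets where ``seq`` matches ``motif``
    under IUPAC degeneracy. The motif may be written with U; the sequence is
    DNA. Invalid IUPAC codes raise ``ValueError``."""
    pattern = _motif_pattern(motif)
    return [m.start() for m in pattern.finditer(seq.upper())]


def motif_frequency(
    clusters: Sequence[PACluster],
    genome: GenomeLike,
    motif: str = "AWTAAA",
    n: int = 50,
) -> tuple[Optional[float], pd.DataFrame]:
    """Fraction of clusters with >= 1 motif hit in their upstream window.

    Returns (fraction, per-cluster table); the fraction is ``None`` for an
    empty cluster set.
    """
    rows = []
    n_hit = 0
    for c in clusters:
        window = extract_upstream(c, genome, n=n)
        offsets = scan_motif(window.seq, motif)
        if offsets:
            n_hit += 1
        rows.append(
            {
                "cluster": c.name,
                "motif": motif.upper().replace("U", "T"),
                "n_hits": len(offsets),
                "offsets": ";".join(map(str, offsets)),
                "window_truncated": window.truncated,
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster", "motif", "n_hits", "offsets", "window_truncated"]
    )
    if not clusters:
        return None, table
    return n_hit / len(clusters), table


PASite = tuple[str, str, int]  # (chrom, strand, coord)


class IntersectionResult(NamedTuple):
    matched: list[tuple[PASite, PASite]]
    only_a: list[PASite]
    only_b: list[PASite]

    @property
    def matched_a(self) -> list[PASite]:
        return [a for a, _ in self.matched]

    @property
    def matched_b(self) -> list[PASite]:
        return [b for _, b in self.matched]


def intersect_pa_sets(
    a: Sequence[PASite], b: Sequence[PASite], tol: int = 25
) -> IntersectionResult:
    """One-to-one nearest-first matching of two PA-site sets.

    Sites match when same-chrom, same-strand and within ``tol`` bases.
    Candidate pairs are consumed greedily by ascending distance (ties broken
    deterministically by position), each site matching at most once, so
    ``|matched| + |only_a| == |A|`` and matched cardinality is symmetric.
    """
    a = list(a)
    b = list(b)
    by_group: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for j, (chrom, strand, coord) in enumerate(b):
        by_group.setdefault((chrom, strand), []).append((coord, j))
    pairs: list[tuple[int, str, str, int, int, int, int]] = []
    for i, (chrom, strand, coord) in enumerate(a):
        for bcoord, j in by_group.get((chrom, strand), []):
            dist = abs(coord - bcoord)
            if dist <= tol:
                pairs.append((dist, chrom, strand, coord, bcoord, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[PASite, PASite]] = []
    for dist, _, _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((a[i], b[j]))
    only_a = [s for i, s in enumerate(a) if i not in used_a]
    only_b = [s for j, s in enumerate(b) if j not in used_b]
    return IntersectionResult(matched, only_a, only_b)


def write_upstream_fasta(
    clusters: Sequence[PACluster],
    genome: GenomeLike,
    path: Union[str, os.PathLike],
    n: int = 50,
) -> None:
    """One FASTA record per cluster (id = cluster name), upstream windows."""
    with atomic_write(path) as fh:
        for c in clusters:
            window = extract_upstream(c, genome, n=n)
            fh.write(f">{c.name}\n{window.seq}\n")
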