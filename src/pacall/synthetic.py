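"""Deterministic synthetic fixture generator for the whole pipeline.

Emulates what a MACE 3'-end library looks like after sequencing:

* a uniform-random genome scrubbed free of natural adenine stretches, so the
  only internal-priming templates are the ones planted deliberately;
* multi-exon gene models (5'UTR, coding exons, introns, a >= 600 nt 3'UTR) on
  both strands, written as GFF3;
* 1-4 planted PA sites per gene — always one at the distal 3'UTR end, plus
  proximal 3'UTR sites and sites in the downstream extension zone;
* an AATAAA poly(A) signal planted 20-30 nt upstream of a configurable
  fraction of sites, with the upstream windows of the remaining sites
  scrubbed motif-free by rejection, so the fixture's expected signal
  frequency is exact;
* predicted miRNA binding sites (BED6, ``mirna|gene`` names) at known 3'UTR
  positions, placed away from every cleavage position so truth loss counts
  are stable under cleavage wobble;
* decoy internal-priming events: planted genomic A10 runs with reads ending
  immediately upstream, indistinguishable from true sites until the
  A-stretch filter sees the reference;
* reads = genomic insert (30-80 nt) + templated poly(A) tail (10-30 nt),
  optionally followed by a low-quality (Q2) terminal segment, with a truth
  SAM of the insert alignments so tests never need an external aligner.

All randomness flows from one seeded generator; equal seeds give
byte-identical output files.

Construction notes that make truth exact rather than approximate: the eight
transcript-orientation bases ending at each plantable cleavage position are
forced to C/G, so the sliding-window tail scan always clips exactly at the
cleavage site for any wobbled read; 4-base C/G guards flank each planted
signal so signal planting can never assemble an adenine stretch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genomic_core import (
    BedRecord,
    GenomicInterval,
    atomic_write,
    reverse_complement,
    write_bed6,
)
from .mirna_loss import MiRNASite
from .annotation import GeneModel
from .preprocess import Read, write_fastq
from .priming_filter import find_a_stretches
from .signal_qc import scan_motif

__all__ = [
    "TruthRecord",
    "SyntheticDataset",
    "make_genome",
    "make_gene_models",
    "simulate_mace_reads",
    "generate_dataset",
    "write_genome_fasta",
    "write_gff3",
    "write_truth_sam",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CG = np.frombuffer(b"CG", dtype=np.uint8)

SIGNAL = "AATAAA"
SIGNAL_MOTIF = "AWTAAA"


@dataclass
class TruthRecord:
    """Ground truth for one planted cleavage site."""

    site_id: str
    gene_symbol: str
    chrom: str
    strand: str
    coord: int  # genomic position of the last transcribed base
    kind: str  # distal | proximal | extension | decoy
    has_signal: bool
    n_mirna_sites_downstream: int
    decoy: bool
    read_count: int = 0
    tail_lengths: list[int] = field(default_factory=list)


@dataclass
class _GeneSpec:
    """Internal bookkeeping: a gene's local layout and genomic anchor."""

    symbol: str
    chrom: str
    strand: str
    g0: int  # genomic start of the gene body
    length: int  # gene body length
    blocks: list[tuple[int, int]]  # local exon blocks, transcription left->right
    cds_lo: int
    cds_hi: int
    utr3_len: int

    def to_ref_point(self, x: int) -> int:
        """Map a transcript-oriented local coordinate to the reference."""
        if self.strand == "+":
            return self.g0 + x
        return self.g0 + self.length - 1 - x

    def to_ref_interval(self, a: int, b: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.g0 + a, self.g0 + b
        return self.g0 + self.length - b, self.g0 + self.length - a


@dataclass
class SyntheticDataset:
    """Everything the generator planted, plus the mutated genome."""

    genome: dict[str, bytearray]
    models: list[GeneModel]
    mirna_sites: list[MiRNASite]
    truth: list[TruthRecord]
    reads: list[Read] = field(default_factory=list)
    sam_records: list[tuple] = field(default_factory=list)
    genes: list[_GeneSpec] = field(default_factory=list)

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.site_id: t for t in self.truth}


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def make_genome(
    n_chroms: int = 1,
    chrom_len: int = 100_000,
    seed: Union[int, np.random.Generator] = 0,
    forbid_a_stretches: bool = True,
) -> dict[str, bytearray]:
    """A reproducible uniform-random genome, optionally stretch-free.

    With ``forbid_a_stretches`` every region matching the internal-priming
    A-stretch definition (10-mer with <= 2 non-A, either strand) is redrawn
    from C/G until the scan is clean, so planted decoys are the only priming
    templates left.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome: dict[str, bytearray] = {}
    for i in range(n_chroms):
        arr = _BASES[rng.integers(0, 4, size=chrom_len)]
        chrom = f"chr{i + 1}"
        if forbid_a_stretches:
            tmp = {chrom: bytearray(arr.tobytes())}
            for _ in range(50):
                stretches = find_a_stretches(tmp)
                if not stretches:
                    break
                buf = np.frombuffer(tmp[chrom], dtype=np.uint8).copy()
                for s in stretches:
                    buf[s.start : s.end] = _CG[rng.integers(0, 2, size=s.end - s.start)]
                tmp[chrom] = bytearray(buf.tobytes())
            genome[chrom] = tmp[chrom]
        else:
            genome[chrom] = bytearray(arr.tobytes())
    return genome


def write_genome_fasta(
    genome: dict[str, bytearray], path: Union[str, os.PathLike], width: int = 80
) -> None:
    with atomic_write(path) as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            text = seq.decode("ascii")
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models, PA sites, miRNA sites, decoys
# ---------------------------------------------------------------------------

_COMPLEMENT_BYTE = {ord("A"): ord("T"), ord("C"): ord("G"),
                    ord("G"): ord("C"), ord("T"): ord("A")}


def _write_transcript_base(genome: dict[str, bytearray], gene: _GeneSpec, x: int, base: str) -> None:
    """Write a transcript-orientation base at local position ``x``."""
    p = gene.to_ref_point(x)
    b = ord(base)
    genome[gene.chrom][p] = b if gene.strand == "+" else _COMPLEMENT_BYTE[b]


def _transcript_seq(genome: dict[str, bytearray], gene: _GeneSpec, a: int, b: int) -> str:
    lo, hi = gene.to_ref_interval(a, b)
    seq = genome[gene.chrom][max(0, lo) : hi].decode("ascii")
    return seq if gene.strand == "+" else reverse_complement(seq)


def _gene_layout(rng: np.random.Generator) -> tuple[list[tuple[int, int]], int, int, int, int]:
    """Random local exon-block layout (transcription left->right)."""
    utr5 = 100
    n_blocks = int(rng.integers(2, 6))
    blocks: list[tuple[int, int]] = []
    first = utr5 + int(rng.integers(150, 351))
    blocks.append((0, first))
    cursor = first
    for _ in range(n_blocks - 2):
        cursor += int(rng.integers(200, 801))
        size = int(rng.integers(150, 351))
        blocks.append((cursor, cursor + size))
        cursor += size
    utr3 = int(rng.integers(600, 1001))
    cursor += int(rng.integers(200, 801))
    last = 100 + utr3
    blocks.append((cursor, cursor + last))
    length = cursor + last
    return blocks, utr5, length - utr3, utr3, length


def _build_model(gene: _GeneSpec) -> GeneModel:
    """The intended GeneModel (what parsing the emitted GFF3 must reproduce)."""
    chrom, strand = gene.chrom, gene.strand

    def iv(a: int, b: int) -> GenomicInterval:
        lo, hi = gene.to_ref_interval(a, b)
        return GenomicInterval(chrom, lo, hi, strand)

    five = [iv(0, gene.cds_lo)]
    exons, three = [], []
    for bs, be in gene.blocks:
        lo, hi = max(bs, gene.cds_lo), min(be, gene.cds_hi)
        if lo < hi:
            exons.append(iv(lo, hi))
        if be > gene.cds_hi:
            three.append(iv(max(bs, gene.cds_hi), be))
    introns = [
        iv(gene.blocks[i][1], gene.blocks[i + 1][0])
        for i in range(len(gene.blocks) - 1)
    ]
    key = lambda v: v.start  # noqa: E731
    return GeneModel(
        gene.symbol, chrom, strand,
        five_utr=sorted(five, key=key), exons=sorted(exons, key=key),
        introns=sorted(introns, key=key), three_utr=sorted(three, key=key),
        transcript_id=f"{gene.symbol}.1",
    )


def _allocate_sites(rng: np.random.Generator, n_genes: int, n_sites: int,
                    max_per_gene: int = 4) -> list[int]:
    if not (n_genes <= n_sites <= n_genes * max_per_gene):
        raise ValueError("n_sites must lie in [n_genes, 4 * n_genes]")
    counts = [1] * n_genes
    extra = n_sites - n_genes
    while extra:
        g = int(rng.integers(0, n_genes))
        if counts[g] < max_per_gene:
            counts[g] += 1
            extra -= 1
    return counts


def make_gene_models(
    genome: dict[str, bytearray],
    n_genes: int = 20,
    n_sites: int = 50,
    signal_fraction: float = 0.6,
    mirna_per_utr: tuple[int, int] = (5, 15),
    n_decoy_sites: int = 5,
    seed: Union[int, np.random.Generator] = 0,
    gene_spacing: int = 10_000,
) -> SyntheticDataset:
    """Plant genes, PA sites, poly(A) signals, miRNA sites and decoys.

    Mutates ``genome`` in place (signal planting, motif scrubbing, cleavage-
    boundary conditioning, decoy A-runs) and returns the dataset with intended
    gene models and truth records. ``signal_fraction`` of all non-decoy sites
    (rounded) receive an AATAAA signal 20-30 nt upstream; the rest get
    motif-free upstream windows by rejection rewriting.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = next(iter(genome))
    chrom_len = len(genome[chrom])

    counts = _allocate_sites(rng, n_genes, n_sites)
    genes: list[_GeneSpec] = []
    site_specs: list[tuple[_GeneSpec, int, str]] = []  # (gene, local coord, kind)
    decoy_runs: list[tuple[int, str]] = []  # (run start, strand)

    cursor = 2_000
    for gi in range(n_genes):
        blocks, cds_lo, cds_hi, utr3, length = _gene_layout(rng)
        strand = "+" if gi % 2 == 0 else "-"
        symbol = f"GENE{gi + 1:03d}"
        gene = _GeneSpec(symbol, chrom, strand, cursor, length, blocks, cds_lo, cds_hi, utr3)
        genes.append(gene)

        # planted PA sites in transcript-local coordinates
        local_sites = [(length - 1, "distal")]
        n_here = counts[gi]
        d1 = int(rng.integers(130, 201))
        if n_here >= 2:
            local_sites.append((length - 1 - d1, "proximal"))
        if n_here >= 3:
            local_sites.append((length - 1 + int(rng.integers(150, 901)), "extension"))
        if n_here >= 4:
            local_sites.append((length - 1 - d1 - int(rng.integers(130, 201)), "proximal"))
        for x, kind in local_sites:
            site_specs.append((gene, x, kind))

        # decoy A-runs go into the gap downstream of the gene body
        cursor += length + gene_spacing
        if cursor + 2_000 > chrom_len:
            raise ValueError(
                f"chrom too short for {n_genes} genes: need > {cursor + 2_000} bp"
            )
    # decoys in the middle of inter-gene gaps, alternating strands
    for di in range(n_decoy_sites):
        gene = genes[di % n_genes]
        gap_lo = gene.g0 + gene.length
        run_start = gap_lo + 4_000 + int(rng.integers(0, 1_000))
        decoy_runs.append((run_start, "+" if di % 2 == 0 else "-"))

    # --- genome surgery -----------------------------------------------------
    # 1. cleavage-boundary conditioning: transcript bases [x-6, x+2] -> C/G
    for gene, x, _ in site_specs:
        for pos in range(x - 6, x + 3):
            _write_transcript_base(genome, gene, pos, "CG"[int(rng.integers(0, 2))])

    # 2. poly(A) signals for the chosen fraction of sites
    order = rng.permutation(len(site_specs))
    n_signal = int(round(signal_fraction * len(site_specs)))
    signal_idx = set(int(i) for i in order[:n_signal])
    for i, (gene, x, _) in enumerate(site_specs):
        if i in signal_idx:
            offset = int(rng.integers(20, 31))  # signal start this far upstream
            start = x - offset
            for j, base in enumerate(SIGNAL):
                _write_transcript_base(genome, gene, start + j, base)
            for pos in list(range(start - 4, start)) + list(range(start + 6, start + 10)):
                _write_transcript_base(genome, gene, pos, "CG"[int(rng.integers(0, 2))])
        else:
            # scrub AWTAAA from the (wobble-widened) upstream window
            lo, hi = x - 53, x + 2
            for _ in range(30):
                window = _transcript_seq(genome, gene, lo, hi)
                hits = scan_motif(window, SIGNAL_MOTIF)
                if not hits:
                    break
                for h in hits:
                    _write_transcript_base(genome, gene, lo + h + 2, "C")

    # 3. decoy adenine runs with non-A upstream guards (transcript orientation)
    buf = genome[chrom]
    for run_start, strand in decoy_runs:
        if strand == "+":
            buf[run_start : run_start + 10] = b"A" * 10
            for p in range(run_start - 9, run_start):
                buf[p] = ord("CG"[int(rng.integers(0, 2))])
        else:
            buf[run_start : run_start + 10] = b"T" * 10
            for p in range(run_start + 10, run_start + 19):
                buf[p] = ord("CG"[int(rng.integers(0, 2))])

    # --- miRNA binding sites ------------------------------------------------
    mirna_sites: list[MiRNASite] = []
    mirna_downstream: dict[int, int] = {}
    site_by_gene: dict[str, list[tuple[int, int, str]]] = {}
    for i, (gene, x, kind) in enumerate(site_specs):
        site_by_gene.setdefault(gene.symbol, []).append((i, x, kind))
    for gene in genes:
        utr_lo = gene.cds_hi
        pa_locals = [x for _, x, _ in site_by_gene[gene.symbol]]
        candidates = [
            p for p in range(utr_lo + 10, gene.length - 20, 12)
            if all(abs(p - x) > 10 and abs(p + 7 - x) > 10 for x in pa_locals)
        ]
        m = int(rng.integers(mirna_per_utr[0], mirna_per_utr[1] + 1))
        m = min(m, len(candidates))
        chosen = sorted(int(c) for c in rng.choice(len(candidates), size=m, replace=False))
        for k, ci in enumerate(chosen):
            p = candidates[ci]
            lo, hi = gene.to_ref_interval(p, p + 7)
            mirna_sites.append(
                MiRNASite(gene.symbol, f"miR-{gene.symbol[4:]}{chr(ord('a') + k)}",
                          GenomicInterval(gene.chrom, lo, hi, gene.strand))
            )
        for i, x, _ in site_by_gene[gene.symbol]:
            mirna_downstream[i] = sum(1 for ci in chosen if candidates[ci] > x)

    # --- truth records ------------------------------------------------------
    truth: list[TruthRecord] = []
    for i, (gene, x, kind) in enumerate(site_specs):
        truth.append(
            TruthRecord(
                site_id=f"S{i + 1:04d}", gene_symbol=gene.symbol, chrom=gene.chrom,
                strand=gene.strand, coord=gene.to_ref_point(x), kind=kind,
                has_signal=i in signal_idx,
                n_mirna_sites_downstream=mirna_downstream[i], decoy=False,
            )
        )
    for di, (run_start, strand) in enumerate(decoy_runs):
        coord = run_start - 1 if strand == "+" else run_start + 10
        truth.append(
            TruthRecord(
                site_id=f"D{di + 1:04d}", gene_symbol=".", chrom=chrom,
                strand=strand, coord=coord, kind="decoy", has_signal=False,
                n_mirna_sites_downstream=0, decoy=True,
            )
        )

    dataset = SyntheticDataset(
        genome=genome, models=[_build_model(g) for g in genes],
        mirna_sites=mirna_sites, truth=truth, genes=genes,
    )
    _validate(dataset, decoy_runs)
    return dataset


def _validate(dataset: SyntheticDataset, decoy_runs: list[tuple[int, str]]) -> None:
    """Construction self-check: decoys are the only A-stretches, true sites
    are far from every stretch, signal windows behave as planted."""
    stretches = find_a_stretches(dataset.genome)
    for s in stretches:
        # windows not touching a planted run were scrubbed out of the genome,
        # so every stretch must sit within one window-length of a run
        if not any(rs - 10 <= s.start and s.end <= rs + 25 for rs, _ in decoy_runs):
            raise RuntimeError(f"unplanned A-stretch at {s.chrom}:{s.start}-{s.end}")
    for t in dataset.truth:
        if t.decoy:
            continue
        for s in stretches:
            if s.start - 25 <= t.coord <= s.end + 25:
                raise RuntimeError(f"true site {t.site_id} too close to an A-stretch")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_mace_reads(
    dataset: SyntheticDataset,
    depth_per_site: int = 50,
    tail_len: tuple[int, int] = (10, 30),
    error_rate: float = 0.0,
    wobble: int = 2,
    insert_len: tuple[int, int] = (30, 80),
    lowq_fraction: float = 0.3,
    lowq_len: tuple[int, int] = (5, 10),
    decoy_read_fraction: float = 0.1,
    seed: Union[int, np.random.Generator] = 0,
) -> SyntheticDataset:
    """Simulate reads for every truth site; fills reads and SAM records.

    Non-decoy sites each get ``depth_per_site`` reads whose cleavage position
    wobbles uniformly within ±``wobble`` nt of truth; decoy sites share
    enough reads that they make up ``decoy_read_fraction`` of the library
    (decoy priming does not wobble: the primer anneals at the stretch).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome = dataset.genome
    real = [t for t in dataset.truth if not t.decoy]
    decoys = [t for t in dataset.truth if t.decoy]
    n_real = depth_per_site * len(real)
    n_decoy = 0
    if decoys and decoy_read_fraction > 0:
        n_decoy = int(round(decoy_read_fraction / (1 - decoy_read_fraction) * n_real))
    plan: list[tuple[TruthRecord, int]] = [(t, depth_per_site) for t in real]
    for k, t in enumerate(decoys):
        share = n_decoy // len(decoys) + (1 if k < n_decoy % len(decoys) else 0)
        plan.append((t, share))

    reads: list[Read] = []
    sam_records: list[tuple] = []
    ridx = 0
    for t, depth in plan:
        t.read_count = depth
        t.tail_lengths = []
        for _ in range(depth):
            ridx += 1
            w = 0 if t.decoy else int(rng.integers(-wobble, wobble + 1))
            coord = t.coord + w
            ins = int(rng.integers(insert_len[0], insert_len[1] + 1))
            if t.strand == "+":
                ref_lo, ref_hi = coord - ins + 1, coord + 1
            else:
                ref_lo, ref_hi = coord, coord + ins
            insert_ref = genome[t.chrom][ref_lo:ref_hi].decode("ascii")
            if error_rate > 0:
                insert_ref = _mutate(insert_ref, error_rate, rng)
            read_seq = insert_ref if t.strand == "+" else reverse_complement(insert_ref)
            tail = int(rng.integers(tail_len[0], tail_len[1] + 1))
            t.tail_lengths.append(tail)
            seq = read_seq + "A" * tail
            quals = [38] * len(seq)
            if rng.random() < lowq_fraction:
                junk = int(rng.integers(lowq_len[0], lowq_len[1] + 1))
                seq += "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=junk))
                quals += [2] * junk
            read_id = f"r{ridx:06d}.{t.site_id}"
            reads.append(Read(read_id, seq, tuple(quals)))
            flag = 0 if t.strand == "+" else 16
            sam_records.append(
                (read_id, flag, t.chrom, ref_lo + 1, 60, f"{ins}M",
                 insert_ref, "".join(chr(38 + 33) for _ in range(ins)))
            )
    dataset.reads = reads
    dataset.sam_records = sam_records
    return dataset


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_gff3(dataset: SyntheticDataset, path: Union[str, os.PathLike]) -> None:
    """Emit gene/mRNA/exon/CDS features (1-based inclusive) for every gene."""
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        for gene in dataset.genes:
            glo, ghi = gene.to_ref_interval(0, gene.length)
            sym, tid = gene.symbol, f"{gene.symbol}.1"
            attrs = f"ID=gene:{sym};Name={sym}"
            fh.write(_gff_line(gene.chrom, "gene", glo, ghi, gene.strand, attrs))
            fh.write(_gff_line(gene.chrom, "mRNA", glo, ghi, gene.strand,
                               f"ID={tid};Parent=gene:{sym}"))
            for bi, (bs, be) in enumerate(gene.blocks):
                lo, hi = gene.to_ref_interval(bs, be)
                fh.write(_gff_line(gene.chrom, "exon", lo, hi, gene.strand,
                                   f"ID={tid}.exon{bi + 1};Parent={tid}"))
                clo, chi_ = max(bs, gene.cds_lo), min(be, gene.cds_hi)
                if clo < chi_:
                    lo, hi = gene.to_ref_interval(clo, chi_)
                    fh.write(_gff_line(gene.chrom, "CDS", lo, hi, gene.strand,
                                       f"ID={tid}.cds{bi + 1};Parent={tid}"))


def _gff_line(chrom: str, ftype: str, lo: int, hi: int, strand: str, attrs: str) -> str:
    frame = "0" if ftype == "CDS" else "."
    return f"{chrom}\tpacall_sim\t{ftype}\t{lo + 1}\t{hi}\t.\t{strand}\t{frame}\t{attrs}\n"


def write_mirna_bed(dataset: SyntheticDataset, path: Union[str, os.PathLike]) -> None:
    write_bed6(
        [
            BedRecord(s.interval.chrom, s.interval.start, s.interval.end,
                      f"{s.mirna_id}|{s.gene_symbol}", "0", s.interval.strand)
            for s in dataset.mirna_sites
        ],
        path,
    )


def write_truth_sam(dataset: SyntheticDataset, path: Union[str, os.PathLike]) -> None:
    with atomic_write(path) as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, seq in dataset.genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for qname, flag, chrom, pos, mapq, cigar, seq, qual in dataset.sam_records:
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )


def write_truth_tsv(dataset: SyntheticDataset, path: Union[str, os.PathLike]) -> None:
    with atomic_write(path) as fh:
        fh.write(
            "site_id\tgene_symbol\tchrom\tstrand\tcoord\tkind\thas_signal\t"
            "n_mirna_sites_downstream\tdecoy\tread_count\ttail_lengths\n"
        )
        for t in dataset.truth:
            tails = ",".join(map(str, t.tail_lengths))
            fh.write(
                f"{t.site_id}\t{t.gene_symbol}\t{t.chrom}\t{t.strand}\t{t.coord}\t"
                f"{t.kind}\t{int(t.has_signal)}\t{t.n_mirna_sites_downstream}\t"
                f"{int(t.decoy)}\t{t.read_count}\t{tails}\n"
            )


DEFAULT_FIXTURE = dict(
    n_genes=20, n_sites=50, signal_fraction=0.6, n_decoy_sites=5,
    depth_per_site=50, wobble=2, decoy_read_fraction=0.1, chrom_len=420_000,
)


def generate_dataset(
    outdir: Optional[Union[str, os.PathLike]] = None,
    seed: int = 42,
    n_genes: int = 20,
    n_sites: int = 50,
    signal_fraction: float = 0.6,
    n_decoy_sites: int = 5,
    depth_per_site: int = 50,
    wobble: int = 2,
    decoy_read_fraction: float = 0.1,
    chrom_len: int = 420_000,
    tail_len: tuple[int, int] = (10, 30),
    error_rate: float = 0.0,
    mirna_per_utr: tuple[int, int] = (5, 15),
) -> SyntheticDataset:
    """Generate the full fixture; optionally write all files to ``outdir``.

    Emits genome.fa, genes.gff3, mirna_sites.bed, reads.fastq, truth.sam and
    truth.tsv. One seeded generator drives everything.
    """
    rng = np.random.default_rng(seed)
    genome = make_genome(1, chrom_len, seed=rng)
    dataset = make_gene_models(
        genome, n_genes=n_genes, n_sites=n_sites, signal_fraction=signal_fraction,
        mirna_per_utr=mirna_per_utr, n_decoy_sites=n_decoy_sites, seed=rng,
    )
    simulate_mace_reads(
        dataset, depth_per_site=depth_per_site, tail_len=tail_len,
        error_rate=error_rate, wobble=wobble,
        decoy_read_fraction=decoy_read_fraction, seed=rng,
    )
    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_genome_fasta(genome, os.path.join(outdir, "genome.fa"))
        write_gff3(dataset, os.path.join(outdir, "genes.gff3"))
        write_mirna_bed(dataset, os.path.join(outdir, "mirna_sites.bed"))
        write_fastq(dataset.reads, os.path.join(outdir, "reads.fastq"))
        write_truth_sam(dataset, os.path.join(outdir, "truth.sam"))
        write_truth_tsv(dataset, os.path.join(outdir, "truth.tsv"))
    return dataset
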