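"""Gene models and hierarchical annotation of PA clusters.

Per transcript the genome is partitioned into 5'UTR, coding exon, intron and
3'UTR intervals (derived from the exon blocks and the coding span), plus a
derived *extension*: the region up to 3 kb downstream of the annotated 3'UTR
that overlaps no annotated feature of any gene on either strand. Extensions
catch PA sites beyond incomplete 3'UTR annotation.

A cluster overlapping several features is reported with the highest class of
the hierarchy ``3'UTR > exon > intron > 5'UTR > extension``; cross-gene ties
at equal rank break by overlap length, then gene symbol. Annotation is
strand-matched: a cluster only annotates to same-strand genes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import gffutils
from intervaltree import IntervalTree

from .clustering import PACluster
from .genomic_core import GenomicInterval

__all__ = [
    "FEATURE_RANK",
    "GeneModel",
    "AnnotatedSite",
    "parse_gene_models",
    "parse_bed12",
    "parse_gff3",
    "build_extensions",
    "AnnotationIndex",
    "annotate_cluster",
    "annotate_clusters",
]

log = logging.getLogger(__name__)

THREE_UTR = "three_utr"
EXON = "exon"
INTRON = "intron"
FIVE_UTR = "five_utr"
EXTENSION = "extension"
UNASSIGNED = "unassigned"

#: hierarchy rank; higher wins
FEATURE_RANK: dict[str, int] = {
    THREE_UTR: 5,
    EXON: 4,
    INTRON: 3,
    FIVE_UTR: 2,
    EXTENSION: 1,
    UNASSIGNED: 0,
}


@dataclass
class GeneModel:
    """Strand-aware feature intervals of one transcript."""

    gene_symbol: str
    chrom: str
    strand: str
    five_utr: list[GenomicInterval] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)  # coding portions
    introns: list[GenomicInterval] = field(default_factory=list)
    three_utr: list[GenomicInterval] = field(default_factory=list)
    extension: Optional[GenomicInterval] = None
    coding: bool = True
    transcript_id: str = ""

    def features(self, include_extension: bool = True) -> Iterable[tuple[str, GenomicInterval]]:
        for iv in self.five_utr:
            yield FIVE_UTR, iv
        for iv in self.exons:
            yield EXON, iv
        for iv in self.introns:
            yield INTRON, iv
        for iv in self.three_utr:
            yield THREE_UTR, iv
        if include_extension and self.extension is not None:
            yield EXTENSION, self.extension

    def three_utr_span(self) -> Optional[GenomicInterval]:
        if not self.three_utr:
            return None
        return GenomicInterval(
            self.chrom,
            min(iv.start for iv in self.three_utr),
            max(iv.end for iv in self.three_utr),
            self.strand,
        )


@dataclass
class AnnotatedSite:
    """A PA cluster with its winning gene/feature assignment."""

    cluster: PACluster
    gene_symbol: str = UNASSIGNED
    feature: str = UNASSIGNED
    hcs: bool = False
    secondary: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _split_blocks(
    blocks: list[tuple[int, int]], cds_lo: int, cds_hi: int, chrom: str, strand: str
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval], list[GenomicInterval]]:
    """Partition exon blocks by the coding span; derive introns from gaps."""
    utr_left: list[GenomicInterval] = []
    coding: list[GenomicInterval] = []
    utr_right: list[GenomicInterval] = []
    for bs, be in blocks:
        if bs < cds_lo:
            utr_left.append(GenomicInterval(chrom, bs, min(be, cds_lo), strand))
        if max(bs, cds_lo) < min(be, cds_hi):
            coding.append(GenomicInterval(chrom, max(bs, cds_lo), min(be, cds_hi), strand))
        if be > cds_hi:
            utr_right.append(GenomicInterval(chrom, max(bs, cds_hi), be, strand))
    introns = [
        GenomicInterval(chrom, blocks[i][1], blocks[i + 1][0], strand)
        for i in range(len(blocks) - 1)
        if blocks[i + 1][0] > blocks[i][1]
    ]
    if strand == "+":
        return utr_left, coding, introns, utr_right
    return utr_right, coding, introns, utr_left


def parse_bed12(path: Union[str, os.PathLike]) -> list[GeneModel]:
    """Parse BED12 transcripts (thickStart/thickEnd = coding span)."""
    models: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_lo, thick_hi = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            models.append(_model_from_blocks(name, chrom, strand, blocks, thick_lo, thick_hi))
    return models


def _model_from_blocks(
    name: str, chrom: str, strand: str, blocks: list[tuple[int, int]],
    cds_lo: int, cds_hi: int, transcript_id: str = "",
) -> GeneModel:
    blocks = sorted(blocks)
    if cds_lo >= cds_hi:  # non-coding: all-exon model, no UTRs
        introns = [
            GenomicInterval(chrom, blocks[i][1], blocks[i + 1][0], strand)
            for i in range(len(blocks) - 1)
            if blocks[i + 1][0] > blocks[i][1]
        ]
        return GeneModel(
            name, chrom, strand,
            exons=[GenomicInterval(chrom, bs, be, strand) for bs, be in blocks],
            introns=introns, coding=False, transcript_id=transcript_id or name,
        )
    five, coding, introns, three = _split_blocks(blocks, cds_lo, cds_hi, chrom, strand)
    return GeneModel(
        name, chrom, strand, five_utr=five, exons=coding, introns=introns,
        three_utr=three, transcript_id=transcript_id or name,
    )


def parse_gff3(path: Union[str, os.PathLike]) -> list[GeneModel]:
    """Parse GFF3 gene models (gene -> mRNA -> exon/CDS) via gffutils."""
    db = gffutils.create_db(
        os.fspath(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            continue
        symbol = None
        for gene in db.parents(mrna, featuretype="gene"):
            symbol = gene.attributes.get("Name", [gene.id])[0]
        if symbol is None:
            symbol = mrna.attributes.get("gene", [mrna.id])[0]
        if cds:
            cds_lo, cds_hi = min(s for s, _ in cds), max(e for _, e in cds)
        else:
            cds_lo = cds_hi = 0
        models.append(
            _model_from_blocks(symbol, mrna.seqid, mrna.strand, sorted(exons),
                               cds_lo, cds_hi, transcript_id=mrna.id)
        )
    return models


def parse_gene_models(path: Union[str, os.PathLike]) -> list[GeneModel]:
    """Parse BED12 or GFF3 gene models (dispatch on extension)."""
    name = os.fspath(path).lower()
    if name.endswith((".gff", ".gff3")):
        return parse_gff3(path)
    return parse_bed12(path)


# ---------------------------------------------------------------------------
# Extensions
# ---------------------------------------------------------------------------


def build_extensions(models: Sequence[GeneModel], max_ext: int = 3000) -> list[GeneModel]:
    """Attach extension intervals (<= ``max_ext`` downstream of each 3'UTR).

    An extension starts at the transcript-orientation end of the 3'UTR and is
    truncated at the first base overlapping *any* annotated feature of any
    gene on either strand; absent when that leaves zero length. Requires all
    models to be loaded first. Returns the same model objects, mutated.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for _, iv in m.features(include_extension=False):
            tree.addi(iv.start, iv.end)
    for m in models:
        m.extension = None
        span = m.three_utr_span()
        if span is None:
            continue
        if m.strand == "+":
            lo, hi = span.end, span.end + max_ext
        else:
            lo, hi = max(0, span.start - max_ext), span.start
        if hi <= lo:
            continue
        for hit in trees.get(m.chrom, IntervalTree()).overlap(lo, hi):
            if m.strand == "+":
                hi = min(hi, hit.begin) if hit.begin >= lo else lo
            else:
                lo = max(lo, hit.end) if hit.end <= hi else hi
        if hi > lo:
            m.extension = GenomicInterval(m.chrom, lo, hi, m.strand)
    return list(models)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


class AnnotationIndex:
    """Interval index over all feature intervals, keyed by (chrom, strand)."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault((m.chrom, m.strand), IntervalTree())
            for cls, iv in m.features():
                tree.addi(iv.start, iv.end, (m.gene_symbol, cls))

    def overlaps(self, chrom: str, strand: str, start: int, end: int):
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [
            (hit.data[0], hit.data[1], max(start, hit.begin), min(end, hit.end))
            for hit in tree.overlap(start, end)
        ]


def annotate_cluster(
    cluster: PACluster,
    index: AnnotationIndex,
    hcs_threshold: int = 5,
) -> AnnotatedSite:
    """Assign the highest-ranking (gene, feature) overlapping the cluster span.

    A single base of overlap with the cluster's [start, end) span suffices.
    Per gene only that gene's highest-ranking class is kept (isoform
    disagreements resolve upward); across genes, ties at equal rank break by
    total overlap length, then lexicographically smaller gene symbol.
    Remaining per-gene pairs become secondary annotations.
    """
    hits = index.overlaps(cluster.chrom, cluster.strand, cluster.start, cluster.end)
    site = AnnotatedSite(cluster, hcs=cluster.is_hcs(hcs_threshold))
    if not hits:
        return site
    # aggregate overlap length per (gene, class)
    overlap_len: dict[tuple[str, str], int] = {}
    for gene, cls, lo, hi in hits:
        overlap_len[(gene, cls)] = overlap_len.get((gene, cls), 0) + (hi - lo)
    # per gene keep the highest-ranking class
    per_gene: dict[str, tuple[str, int]] = {}
    for (gene, cls), length in overlap_len.items():
        cur = per_gene.get(gene)
        if cur is None or FEATURE_RANK[cls] > FEATURE_RANK[cur[0]] or (
            cls == cur[0] and length > cur[1]
        ):
            per_gene[gene] = (cls, length)
    ranked = sorted(
        per_gene.items(),
        key=lambda kv: (-FEATURE_RANK[kv[1][0]], -kv[1][1], kv[0]),
    )
    best_gene, (best_cls, _) = ranked[0]
    site.gene_symbol = best_gene
    site.feature = best_cls
    site.secondary = [(g, cls) for g, (cls, _) in ranked[1:]]
    cluster.feature = best_cls
    cluster.gene_symbol = best_gene
    return site


def annotate_clusters(
    clusters: Sequence[PACluster],
    models: Sequence[GeneModel],
    max_ext: int = 3000,
    hcs_threshold: int = 5,
) -> list[AnnotatedSite]:
    """Build extensions, index all models and annotate every cluster."""
    build_extensions(models, max_ext=max_ext)
    index = AnnotationIndex(models)
    return [annotate_cluster(c, index, hcs_threshold) for c in clusters]
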